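import numpy as np
import pytest

from docfc.atlas import ROIAtlas
from docfc.cohort import generate_atlas


@pytest.fixture
def atlas4() -> ROIAtlas:
    """Minimal valid bilateral atlas: 2 homologue pairs."""
    return ROIAtlas(
        names=("A_L", "A_R", "B_L", "B_R"),
        hemisphere=np.array(["L", "R", "L", "R"]),
        homologue=np.array([1, 0, 3, 2]),
        centroids=np.array([[-10.0, 0, 0], [10.0, 0, 0],
                            [-30.0, 20, 5], [30.0, 20, 5]]),
        size_voxels=np.array([100, 100, 200, 200]),
    )


@pytest.fixture(scope="session")
def atlas90() -> ROIAtlas:
    return generate_atlas(90, seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
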