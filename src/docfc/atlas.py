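"""Bilateral ROI atlas: hemispheres, homologue pairing, pair categories, geometry.

The parcellation model mirrors a 90-area bilateral atlas (45 regions per
hemisphere, each with a mirror-image homologue in the opposite hemisphere).
Region pairs are classified into the categories used throughout the
connectivity analyses:

undirected (symmetric measures such as partial correlation)
    HIH  homologue inter-hemispheric (a region and its mirror region)
    LL   left intra-hemispheric
    RR   right intra-hemispheric
    LR   non-homologue inter-hemispheric

directed (asymmetric measures such as transfer entropy)
    HLR / HRL  homologue pairs, left-to-right / right-to-left
    LL / RR    intra-hemispheric
    LR / RL    non-homologue inter-hemispheric, by direction

Homologue pairs are *excluded* from LR/RL so that the category means are
computed over disjoint pair sets.  TOTAL covers every off-diagonal pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNDIRECTED_CATEGORIES: tuple[str, ...] = ("HIH", "LL", "RR", "LR")
DIRECTED_CATEGORIES: tuple[str, ...] = ("HLR", "HRL", "LL", "RR", "LR", "RL")
TOTAL: str = "TOTAL"

ATLAS_COLUMNS = ["roi_id", "name", "hemisphere", "homologue_id",
                 "x", "y", "z", "size_voxels"]


class AtlasValidationError(ValueError):
    """Raised when an atlas table violates the bilateral-parcellation invariants."""


@dataclass(frozen=True)
class ROIAtlas:
    """Validated bilateral parcellation.

    Internally regions are indexed 0..N-1 (contiguous); ``homologue`` holds
    the internal index of each region's mirror region, or -1 for a strictly
    unilateral region.  ``original_ids`` preserves the ids of the source
    table so files written back out round-trip.
    """

    names: tuple[str, ...]
    hemisphere: np.ndarray        # shape (N,), '<U1', values 'L'/'R'
    homologue: np.ndarray         # shape (N,), int, -1 = no homologue
    centroids: np.ndarray         # shape (N, 3), MNI mm
    size_voxels: np.ndarray       # shape (N,), positive int
    original_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.names)
        object.__setattr__(self, "hemisphere", np.asarray(self.hemisphere, dtype="<U1"))
        object.__setattr__(self, "homologue", np.asarray(self.homologue, dtype=int))
        object.__setattr__(self, "centroids", np.asarray(self.centroids, dtype=float))
        object.__setattr__(self, "size_voxels", np.asarray(self.size_voxels, dtype=int))
        if self.original_ids is None:
            object.__setattr__(self, "original_ids", np.arange(n))
        else:
            object.__setattr__(self, "original_ids", np.asarray(self.original_ids, dtype=int))
        self._validate()

    @property
    def n_rois(self) -> int:
        return len(self.names)

    def _validate(self) -> None:
        n = self.n_rois
        if self.hemisphere.shape != (n,) or self.homologue.shape != (n,):
            raise AtlasValidationError("hemisphere/homologue length must match names")
        if self.centroids.shape != (n, 3):
            raise AtlasValidationError("centroids must be an (N, 3) array of MNI mm")
        if self.size_voxels.shape != (n,) or np.any(self.size_voxels <= 0):
            raise AtlasValidationError("size_voxels must be positive for every region")
        bad_hemi = ~np.isin(self.hemisphere, ("L", "R"))
        if np.any(bad_hemi):
            raise AtlasValidationError(
                f"hemisphere must be 'L' or 'R'; offending rows: {np.where(bad_hemi)[0].tolist()}")
        for i, h in enumerate(self.homologue):
            if h == -1:
                continue
            if not (0 <= h < n):
                raise AtlasValidationError(
                    f"region {i} ({self.names[i]}): homologue index {h} out of range")
            if self.homologue[h] != i:
                raise AtlasValidationError(
                    f"region {i} ({self.names[i]}): homologue pairing is not an involution "
                    f"(homologue {h} points back to {self.homologue[h]})")
            if h == i:
                raise AtlasValidationError(
                    f"region {i} ({self.names[i]}): region cannot be its own homologue")
            if self.hemisphere[h] == self.hemisphere[i]:
                raise AtlasValidationError(
                    f"region {i} ({self.names[i]}) and homologue {h} ({self.names[h]}) "
                    f"are both in hemisphere {self.hemisphere[i]}")

    # ------------------------------------------------------------------ geometry

    def distance_matrix(self) -> np.ndarray:
        """Pairwise Euclidean distances (mm) between region centroids."""
        diff = self.centroids[:, None, :] - self.centroids[None, :, :]
        return np.sqrt((diff ** 2).sum(axis=-1))

    def inter_roi_distance(self, i: int, j: int) -> float:
        """Euclidean centroid distance (mm) between regions ``i`` and ``j``."""
        self._check_id(i)
        self._check_id(j)
        return float(np.linalg.norm(self.centroids[i] - self.centroids[j]))

    def _check_id(self, i: int) -> None:
        if not (0 <= i < self.n_rois):
            raise IndexError(f"roi index {i} out of range for {self.n_rois}-region atlas")

    # ------------------------------------------------------------------ categories

    def pair_category(self, source: int, target: int, directed: bool = True) -> str:
        """Classify the ordered pair ``source -> target``.

        With ``directed=False`` the homologue labels collapse to HIH and
        LR/RL collapse to LR.  The diagonal belongs to no category.
        """
        self._check_id(source)
        self._check_id(target)
        if source == target:
            raise ValueError("the diagonal (source == target) belongs to no category")
        hs, ht = self.hemisphere[source], self.hemisphere[target]
        homologous = self.homologue[source] == target
        if homologous:
            if not directed:
                return "HIH"
            return "HLR" if hs == "L" else "HRL"
        if hs == ht:
            return "LL" if hs == "L" else "RR"
        if not directed:
            return "LR"
        return "LR" if hs == "L" else "RL"

    def category_masks(self, directed: bool = True) -> dict[str, np.ndarray]:
        """Boolean ``(N, N)`` masks per category.

        Entry ``mask[i, j]`` refers to the ordered pair source ``j`` ->
        target ``i`` for directed masks, matching the connectivity-matrix
        convention where ``values[i, j]`` is the flow from j to i.  For
        undirected masks only the upper triangle ``i < j`` is set, so each
        unordered pair is counted once.  TOTAL covers all off-diagonal
        (ordered or unordered) pairs.
        """
        n = self.n_rois
        hemi_l = self.hemisphere == "L"
        src_l = hemi_l[None, :]          # column index j = source
        tgt_l = hemi_l[:, None]          # row index i = target
        homol = np.zeros((n, n), dtype=bool)
        has = self.homologue >= 0
        homol[self.homologue[has], np.arange(n)[has]] = True
        off = ~np.eye(n, dtype=bool)
        same = src_l == tgt_l
        masks: dict[str, np.ndarray]
        if directed:
            masks = {
                "HLR": homol & src_l & ~tgt_l,
                "HRL": homol & ~src_l & tgt_l,
                "LL": off & same & src_l,
                "RR": off & same & ~src_l,
                "LR": ~homol & ~same & src_l,
                "RL": ~homol & ~same & ~src_l,
                TOTAL: off,
            }
        else:
            triu = np.triu(np.ones((n, n), dtype=bool), k=1)
            masks = {
                "HIH": (homol | homol.T) & triu,
                "LL": same & src_l & triu,
                "RR": same & ~src_l & triu,
                "LR": ~(homol | homol.T) & ~same & triu,
                TOTAL: triu,
            }
        return masks

    # ------------------------------------------------------------------ i/o

    def to_frame(self) -> pd.DataFrame:
        homol_ids = np.where(self.homologue >= 0,
                             self.original_ids[np.clip(self.homologue, 0, None)], -1)
        return pd.DataFrame({
            "roi_id": self.original_ids,
            "name": list(self.names),
            "hemisphere": self.hemisphere,
            "homologue_id": homol_ids,
            "x": self.centroids[:, 0],
            "y": self.centroids[:, 1],
            "z": self.centroids[:, 2],
            "size_voxels": self.size_voxels,
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def load_atlas(path) -> ROIAtlas:
    """Read and validate an atlas sidecar TSV.

    Required columns: roi_id, name, hemisphere, homologue_id, x, y, z,
    size_voxels.  Ids may be any unique integers; they are remapped to a
    contiguous 0-based internal index.  ``homologue_id`` of -1 (or empty)
    marks a strictly unilateral region.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ATLAS_COLUMNS if c not in df.columns]
    if missing:
        raise AtlasValidationError(f"atlas table missing columns: {missing}")
    ids = df["roi_id"].to_numpy()
    if len(np.unique(ids)) != len(ids):
        dup = ids[pd.Series(ids).duplicated()].tolist()
        raise AtlasValidationError(f"duplicate roi_id values: {dup}")
    index_of = {int(v): k for k, v in enumerate(ids)}
    homol = np.full(len(ids), -1, dtype=int)
    raw_h = df["homologue_id"].fillna(-1).to_numpy()
    for row, h in enumerate(raw_h):
        h = int(h)
        if h == -1:
            continue
        if h not in index_of:
            raise AtlasValidationError(
                f"row {row} (roi_id {int(ids[row])}): homologue_id {h} "
                f"references a missing region")
        homol[row] = index_of[h]
    return ROIAtlas(
        names=tuple(df["name"].astype(str)),
        hemisphere=df["hemisphere"].to_numpy(dtype="<U1"),
        homologue=homol,
        centroids=df[["x", "y", "z"]].to_numpy(dtype=float),
        size_voxels=df["size_voxels"].to_numpy(dtype=int),
        original_ids=ids.astype(int),
    )
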