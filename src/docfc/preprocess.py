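"""Scan container and minimal signal conditioning.

Conditioning is deliberately light: the heavy image-space preprocessing
(realignment, spatial normalisation, smoothing) is assumed done upstream;
here we only remove a least-squares linear trend and apply a zero-phase
band-pass to the slow fluctuation band of interest (0.01-0.08 Hz by
default).  A zero-phase forward-backward Butterworth filter is used so the
temporal lags that the directed-connectivity estimator relies on are not
distorted by filter phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

#: CRS-R behavioural subscales and their maximum scores (total 23).
CRSR_SUBSCALES: dict[str, int] = {
    "auditory": 4,
    "visual": 5,
    "motor": 6,
    "oromotor_verbal": 3,
    "communication": 2,
    "arousal": 3,
}

MIN_TIMEPOINTS = 64


@dataclass
class ScanSeries:
    """One scan's region-by-time matrix plus subject metadata.

    ``matrix`` has shape (T, N): rows are time points, columns are regions
    aligned to the atlas order.  ``crsr`` holds the six CRS-R subscale
    scores plus ``total`` for patient scans, or None for controls.
    """

    subject_id: str
    condition: str
    matrix: np.ndarray
    tr: float
    roi_names: tuple[str, ...]
    crsr: dict[str, int] | None = None
    months_since_injury: float | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("scan matrix must be 2-D (time x regions)")
        if self.matrix.shape[1] != len(self.roi_names):
            raise ValueError(
                f"scan has {self.matrix.shape[1]} columns but {len(self.roi_names)} ROI names")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError(f"scan {self.subject_id}: non-finite values in time series")
        if self.tr <= 0:
            raise ValueError("tr must be positive (seconds)")

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_rois(self) -> int:
        return self.matrix.shape[1]

    def require_length(self, minimum: int = MIN_TIMEPOINTS) -> None:
        if self.n_timepoints < minimum:
            raise ValueError(
                f"scan {self.subject_id}: {self.n_timepoints} time points, "
                f"need at least {minimum} for entropy estimation")

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, columns=list(self.roi_names)).to_csv(
            path, sep="\t", index=False, float_format="%.10g")


def read_scan(path, *, subject_id: str, condition: str, tr: float,
              crsr: dict[str, int] | None = None,
              months_since_injury: float | None = None) -> ScanSeries:
    """Load a per-subject TSV (rows = time points, columns = ROI names)."""
    df = pd.read_csv(path, sep="\t")
    return ScanSeries(subject_id=subject_id, condition=condition,
                      matrix=df.to_numpy(dtype=float), tr=tr,
                      roi_names=tuple(df.columns), crsr=crsr,
                      months_since_injury=months_since_injury)


def roi_average(voxel_matrix: np.ndarray, labels: np.ndarray, n_rois: int) -> np.ndarray:
    """Average voxel time series into per-region series.

    ``labels`` assigns each of the V columns of ``voxel_matrix`` (T x V) to
    a region index in ``0..n_rois-1``; column r of the result is the
    unweighted mean over voxels labelled r.  Every region must own at least
    one voxel.
    """
    voxel_matrix = np.asarray(voxel_matrix, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if voxel_matrix.ndim != 2 or labels.shape != (voxel_matrix.shape[1],):
        raise ValueError("voxel_matrix must be (T, V) with one label per voxel column")
    counts = np.bincount(labels, minlength=n_rois)
    empty = np.where(counts[:n_rois] == 0)[0]
    if empty.size:
        raise ValueError(f"regions with zero labelled voxels: {empty.tolist()}")
    out = np.zeros((voxel_matrix.shape[0], n_rois))
    for r in range(n_rois):
        out[:, r] = voxel_matrix[:, labels == r].mean(axis=1)
    return out


def detrend_bandpass(series: np.ndarray, tr: float,
                     low: float = 0.01, high: float = 0.08,
                     order: int = 4) -> np.ndarray:
    """Linear detrend then zero-phase Butterworth band-pass.

    Works on a single series (T,) or a multi-channel matrix (T, N), per
    column.  ``low`` and ``high`` are in Hz and must lie strictly inside
    (0, Nyquist) with ``low < high``.
    """
    x = np.asarray(series, dtype=float)
    t_len = x.shape[0]
    if t_len < 16:
        raise ValueError("need at least 16 time points to filter")
    nyq = 1.0 / (2.0 * tr)
    if not (0.0 < low < high):
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz >= Nyquist {nyq} Hz at TR {tr} s")
    x = signal.detrend(x, axis=0, type="linear")
    sos = signal.butter(order, [low / nyq, high / nyq], btype="bandpass", output="sos")
    padlen = min(3 * (2 * sos.shape[0] + 1), t_len - 1)
    return signal.sosfiltfilt(sos, x, axis=0, padlen=padlen)


def standardize(series: np.ndarray) -> np.ndarray:
    """Z-score per column; a zero-variance column maps to all zeros."""
    x = np.asarray(series, dtype=float)
    mean = x.mean(axis=0, keepdims=True) if x.ndim == 2 else x.mean()
    sd = x.std(axis=0, keepdims=True) if x.ndim == 2 else x.std()
    sd = np.where(np.asarray(sd) == 0, 1.0, sd)
    return (x - mean) / sd
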