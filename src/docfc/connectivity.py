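"""Functional-connectivity estimators: partial correlation and transfer entropy.

Two complementary measures of statistical dependence between regional
time series:

* **Partial correlation (PC)** — the correlation between two regions after
  removing the linear contribution of every other region, obtained from the
  precision matrix P = C^-1 as ``PC_ij = -P_ij / sqrt(P_ii P_jj)``.
  Symmetric; significance from the standard t statistic with
  ``df = T - 2 - (N - 2)`` controlled variables.

* **Transfer entropy (TE)** — the reduction, in bits, of uncertainty about
  a target region's future given the source region's past, beyond what the
  target's own past provides:

      TE(j -> i) = H(iF | iP) - H(iF | iP, jP)

  with iP/jP the (discretised) present series and iF the target series
  circularly shifted forward by ``lag`` samples.  Probabilities are plug-in
  (empirical histogram) estimates after rounding each z-scored series,
  multiplied by ``scale``, to the nearest integer (ties away from zero).
  Directed and nonnegative by construction.  Significance comes from a
  permutation null obtained by shuffling the *target* series, which
  destroys its temporal structure while keeping the source fixed.

The plug-in estimator is biased upward at short series; the bias is shared
by every pair and by the permutation null, so within-scan comparisons and
group contrasts at matched series length remain meaningful.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ScanSeries, standardize

DEFAULT_LAG = 10          # samples; 20 s at TR = 2 s
DEFAULT_SCALE = 3.0       # applied to z-scored series before integer rounding
DEFAULT_RIDGE = 1e-8
LOG_BASE_NOTE = "log base 2 (bits) throughout"


@dataclass
class ConnectivityResult:
    """One scan's connectivity matrices plus estimator parameters.

    ``values[i, j]`` is the coupling from source j to target i (TE) or the
    symmetric pair value (PC/C); the diagonal is NaN-masked.  ``pvalues``
    is aligned to ``values``.
    """

    measure: str                       # "PC", "C" or "TE"
    values: np.ndarray
    pvalues: np.ndarray | None
    roi_names: tuple[str, ...]
    params: dict = field(default_factory=dict)
    subject_id: str | None = None
    condition: str | None = None

    @property
    def directed(self) -> bool:
        return self.measure == "TE"

    def save(self, out_dir, stem: str | None = None) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        stem = stem or f"{self.subject_id}_{self.measure.lower()}"
        names = list(self.roi_names)
        pd.DataFrame(self.values, index=names, columns=names).to_csv(
            out_dir / f"{stem}_values.tsv", sep="\t", float_format="%.10g")
        if self.pvalues is not None:
            pd.DataFrame(self.pvalues, index=names, columns=names).to_csv(
                out_dir / f"{stem}_pvalues.tsv", sep="\t", float_format="%.10g")
        meta = {"measure": self.measure, "subject_id": self.subject_id,
                "condition": self.condition, **self.params}
        (out_dir / f"{stem}_params.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, out_dir, stem: str) -> "ConnectivityResult":
        out_dir = Path(out_dir)
        values = pd.read_csv(out_dir / f"{stem}_values.tsv", sep="\t", index_col=0)
        p_path = out_dir / f"{stem}_pvalues.tsv"
        pvalues = (pd.read_csv(p_path, sep="\t", index_col=0).to_numpy()
                   if p_path.exists() else None)
        meta = json.loads((out_dir / f"{stem}_params.json").read_text())
        return cls(meta.pop("measure"), values.to_numpy(), pvalues,
                   tuple(values.columns),
                   subject_id=meta.pop("subject_id", None),
                   condition=meta.pop("condition", None), params=meta)


# --------------------------------------------------------------------------
# correlation / partial correlation
# --------------------------------------------------------------------------

def _as_matrix(scan) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(scan, ScanSeries):
        return scan.matrix, scan.roi_names
    x = np.asarray(scan, dtype=float)
    return x, tuple(f"roi_{k}" for k in range(x.shape[1]))


def correlation_matrix(scan) -> np.ndarray:
    """Pearson correlation between all region pairs (unit diagonal)."""
    x, names = _as_matrix(scan)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 time points for a correlation")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = [names[k] for k in np.where(sd == 0)[0]]
        raise ValueError(f"constant time series for ROI(s): {bad}")
    c = np.corrcoef(x, rowvar=False)
    return np.atleast_2d(c)


def partial_correlation(C: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """Partial-correlation matrix from a correlation matrix.

    ``PC_ij = -P_ij / sqrt(P_ii P_jj)`` with ``P = (C + ridge*I)^-1``.
    The diagonal is NaN-masked.  A singular C with ``ridge=0`` is an error;
    pass a small ridge (e.g. 1e-8) to regularise ill-conditioned matrices.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("C must be square")
    if not np.allclose(C, C.T, atol=1e-10) or not np.allclose(np.diag(C), 1.0, atol=1e-8):
        raise ValueError("C must be symmetric with unit diagonal")
    if ridge < 0:
        raise ValueError("ridge must be nonnegative")
    creg = C + ridge * np.eye(C.shape[0])
    if np.linalg.cond(creg) > 1e13:
        raise np.linalg.LinAlgError(
            "correlation matrix is singular or near-singular; pass a small "
            "ridge (e.g. 1e-8) to regularise")
    P = np.linalg.inv(creg)
    d = np.sqrt(np.diag(P))
    pc = -P / np.outer(d, d)
    np.fill_diagonal(pc, np.nan)
    return pc


def pc_pvalues(PC: np.ndarray, n_samples: int, n_controlled: int) -> np.ndarray:
    """Two-sided p-values for the null of zero partial correlation.

    Uses ``t = PC * sqrt(df / (1 - PC^2))`` with
    ``df = n_samples - 2 - n_controlled`` degrees of freedom.
    """
    df = n_samples - 2 - n_controlled
    if df < 1:
        raise ValueError(f"degrees of freedom {df} < 1 "
                         f"(n_samples={n_samples}, n_controlled={n_controlled})")
    pc = np.asarray(PC, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.clip(pc ** 2, 0.0, 1.0)
        t = pc * np.sqrt(df / np.where(r2 >= 1.0, np.nan, 1.0 - r2))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(r2 >= 1.0, 0.0, p)
    p[np.isnan(pc)] = np.nan
    return p


def pc_connectivity(scan: ScanSeries, ridge: float = DEFAULT_RIDGE) -> ConnectivityResult:
    """Partial-correlation result (values + p-values) for one scan."""
    c = correlation_matrix(scan)
    pc = partial_correlation(c, ridge=ridge)
    n = pc.shape[0]
    p = pc_pvalues(pc, scan.n_timepoints, n_controlled=n - 2)
    return ConnectivityResult("PC", pc, p, scan.roi_names,
                              params={"ridge": ridge, "n_samples": scan.n_timepoints},
                              subject_id=scan.subject_id, condition=scan.condition)


def c_connectivity(scan: ScanSeries) -> ConnectivityResult:
    """Plain-correlation result for one scan (diagonal NaN-masked)."""
    c = correlation_matrix(scan).copy()
    np.fill_diagonal(c, np.nan)
    p = pc_pvalues(c, scan.n_timepoints, n_controlled=0)
    return ConnectivityResult("C", c, p, scan.roi_names,
                              params={"n_samples": scan.n_timepoints},
                              subject_id=scan.subject_id, condition=scan.condition)


# --------------------------------------------------------------------------
# discrete entropies
# --------------------------------------------------------------------------

def discretize_round(series: np.ndarray, scale: float = 1.0) -> np.ndarray:
    """Map each value v to the nearest integer of ``v * scale``.

    Half-integers round *away from zero* (so 0.5 -> 1, -0.5 -> -1); the
    platform default banker's rounding would silently change the discrete
    alphabet.  A degenerate result (single state from a varying input)
    triggers a warning.
    """
    x = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("series must be finite")
    scaled = x * scale
    out = np.sign(scaled) * np.floor(np.abs(scaled) + 0.5)
    out = out.astype(np.int64)
    if x.size > 1 and np.ptp(x) > 0 and np.ptp(out) == 0:
        warnings.warn("discretisation collapsed a varying series to a single "
                      "state; consider a larger scale", stacklevel=2)
    return out


def _codes(values: np.ndarray) -> tuple[np.ndarray, int]:
    """Dense 0..K-1 codes (order-preserving) and alphabet size."""
    uniq, codes = np.unique(np.asarray(values).ravel(), return_inverse=True)
    return codes.astype(np.int64), len(uniq)


def _entropy_from_codes(codes: np.ndarray, n_bins: int) -> float:
    counts = np.bincount(codes, minlength=n_bins)
    counts = counts[counts > 0]
    p = counts / codes.size
    return float(-(p * np.log2(p)).sum())


def _joint_codes(vectors: list[np.ndarray]) -> tuple[np.ndarray, int]:
    """Combine aligned code vectors into one monotone joint code."""
    code, k = _codes(vectors[0])
    for v in vectors[1:]:
        c2, k2 = _codes(v)
        code = code * k2 + c2
        k = k * k2
    return code, k


def shannon_entropy(*symbol_vectors: np.ndarray) -> float:
    """Plug-in joint Shannon entropy (bits) of aligned discrete vectors."""
    if not symbol_vectors:
        raise ValueError("need at least one symbol vector")
    vecs = [np.asarray(v) for v in symbol_vectors]
    n = vecs[0].shape[0]
    if n == 0:
        raise ValueError("symbol vectors must be nonempty")
    if any(v.shape[0] != n for v in vecs):
        raise ValueError("symbol vectors must have equal length")
    code, k = _joint_codes(vecs)
    return _entropy_from_codes(code, k)


def conditional_entropy(x: np.ndarray, *given: np.ndarray) -> float:
    """Plug-in H(X | given...) = H(X, given) - H(given), in bits."""
    if not given:
        return shannon_entropy(x)
    x = np.asarray(x)
    if any(np.asarray(g).shape[0] != x.shape[0] for g in given):
        raise ValueError("conditioning vectors must match the length of x")
    h_joint = shannon_entropy(x, *given)
    h_given = shannon_entropy(*given)
    return max(h_joint - h_given, 0.0)


# --------------------------------------------------------------------------
# transfer entropy
# --------------------------------------------------------------------------

def _prepare_codes(series: np.ndarray, scale: float, standardize_first: bool
                   ) -> tuple[np.ndarray, int]:
    x = np.asarray(series, dtype=float)
    if standardize_first:
        x = standardize(x)
    return _codes(discretize_round(x, scale))


def _future(codes: np.ndarray, lag: int, mode: str) -> tuple[np.ndarray, np.ndarray, slice]:
    """(iF, iP, past-slice) under the chosen future construction.

    circular: iF(t) = x(t + lag) with wrap-around (all T samples kept).
    truncate: drop the wrapped samples (T - lag samples).
    """
    if mode == "circular":
        return np.roll(codes, -lag), codes, slice(None)
    if mode == "truncate":
        return codes[lag:], codes[:-lag], slice(0, codes.size - lag)
    raise ValueError(f"unknown future mode {mode!r}")


def transfer_entropy(target: np.ndarray, source: np.ndarray, lag: int = DEFAULT_LAG,
                     scale: float = DEFAULT_SCALE, standardize_first: bool = True,
                     future_mode: str = "circular") -> float:
    """TE from ``source`` to ``target`` in bits (plug-in estimator).

    Both series are (optionally z-scored and) integer-discretised; the
    target's future is its series shifted forward by ``lag`` samples
    (circularly by default).  Identical source and target give exactly 0:
    conditioning on a copy of the target's own past adds nothing.
    """
    target = np.asarray(target, dtype=float)
    source = np.asarray(source, dtype=float)
    if target.shape != source.shape or target.ndim != 1:
        raise ValueError("target and source must be 1-D series of equal length")
    if not (0 < lag < target.size):
        raise ValueError(f"lag must be in (0, T); got lag={lag}, T={target.size}")
    tc, kt = _prepare_codes(target, scale, standardize_first)
    sc, ks = _prepare_codes(source, scale, standardize_first)
    i_f, i_p, past = _future(tc, lag, future_mode)
    j_p = sc[past]
    # Monotone joint coding keeps the count vectors (hence the float
    # entropies) bit-identical when source == target, so TE cancels to 0.0.
    pair = i_f * kt + i_p
    cond1 = (_entropy_from_codes(pair, kt * kt)
             - _entropy_from_codes(i_p, kt))
    trip = pair * ks + j_p
    pair2 = i_p * ks + j_p
    cond2 = (_entropy_from_codes(trip, kt * kt * ks)
             - _entropy_from_codes(pair2, kt * ks))
    return max(cond1 - cond2, 0.0)


def te_matrix(scan, lag: int = DEFAULT_LAG, scale: float = DEFAULT_SCALE,
              standardize_first: bool = True, future_mode: str = "circular"
              ) -> np.ndarray:
    """All-pairs TE matrix; entry [i, j] = TE from source j to target i."""
    x, _names = _as_matrix(scan)
    t_len, n = x.shape
    if not (0 < lag < t_len):
        raise ValueError(f"lag must be in (0, T); got lag={lag}, T={t_len}")
    codes = []
    for k in range(n):
        codes.append(_prepare_codes(x[:, k], scale, standardize_first))
    out = np.full((n, n), np.nan)
    for i in range(n):
        tc, kt = codes[i]
        i_f, i_p, past = _future(tc, lag, future_mode)
        pair = i_f * kt + i_p
        cond1 = (_entropy_from_codes(pair, kt * kt)
                 - _entropy_from_codes(i_p, kt))
        for j in range(n):
            if j == i:
                continue
            sc, ks = codes[j]
            j_p = sc[past]
            trip = pair * ks + j_p
            pair2 = i_p * ks + j_p
            cond2 = (_entropy_from_codes(trip, kt * kt * ks)
                     - _entropy_from_codes(pair2, kt * ks))
            out[i, j] = max(cond1 - cond2, 0.0)
    return out


def _rowwise_entropy(codes2d: np.ndarray) -> np.ndarray:
    """Entropy (bits) of each row of an (R, T) integer code matrix.

    Counts symbol runs after a per-row sort, which is much cheaper than a
    histogram when the alphabet is large relative to the row length:
    H = log2(T) - (1/T) * sum_c c*log2(c) over run lengths c.
    """
    s = np.sort(codes2d, axis=1)
    r, t_len = s.shape
    new = np.ones((r, t_len), dtype=bool)
    new[:, 1:] = s[:, 1:] != s[:, :-1]
    starts = np.flatnonzero(new.ravel())       # rows are contiguous blocks
    lengths = np.diff(np.append(starts, r * t_len)).astype(float)
    terms = lengths * np.log2(lengths)
    row = starts // t_len
    return np.log2(t_len) - np.bincount(row, weights=terms, minlength=r) / t_len


def te_shuffle_pvalues(scan, lag: int = DEFAULT_LAG, scale: float = DEFAULT_SCALE,
                       n_permutations: int = 100, seed=None,
                       standardize_first: bool = True, future_mode: str = "circular",
                       observed: np.ndarray | None = None) -> np.ndarray:
    """Permutation p-values for every ordered pair's TE.

    For each pair (source j -> target i) the *target* series is randomly
    permuted ``n_permutations`` times (destroying its temporal structure;
    the source stays fixed) and the TE recomputed each time.  The add-one
    p-value ``(1 + #{TE_perm >= TE_obs}) / (1 + n_permutations)`` never
    reaches zero.  Permutations are shared across sources for a given
    target, which is what makes the all-pairs computation tractable.
    """
    if n_permutations < 19:
        raise ValueError("need at least 19 permutations for a p-value at alpha 0.1")
    x, _names = _as_matrix(scan)
    t_len, n = x.shape
    rng = np.random.default_rng(seed)
    if observed is None:
        observed = te_matrix(x, lag=lag, scale=scale,
                             standardize_first=standardize_first, future_mode=future_mode)
    codes = [_prepare_codes(x[:, k], scale, standardize_first) for k in range(n)]
    pvals = np.full((n, n), np.nan)
    r = n_permutations
    for i in range(n):
        tc, kt = codes[i]
        perms = np.argsort(rng.random((r, t_len)), axis=1)
        i_p = tc[perms]                                   # (R, T)
        if future_mode == "circular":
            i_f = np.roll(i_p, -lag, axis=1)
            i_pp, j_slice = i_p, slice(None)
            # every permutation has the same marginal multiset
            h_ip = np.full(r, _entropy_from_codes(tc, kt))
        else:
            i_f, i_pp, j_slice = i_p[:, lag:], i_p[:, :-lag], slice(0, t_len - lag)
            h_ip = _rowwise_entropy(i_pp)
        pair = i_f * kt + i_pp
        cond1 = _rowwise_entropy(pair) - h_ip
        for j in range(n):
            if j == i:
                continue
            sc, ks = codes[j]
            j_p = sc[j_slice][None, :]
            trip = pair * ks + j_p
            pair2 = i_pp * ks + j_p
            cond2 = _rowwise_entropy(trip) - _rowwise_entropy(pair2)
            te_null = np.maximum(cond1 - cond2, 0.0)
            exceed = int(np.sum(te_null >= observed[i, j] - 1e-12))
            pvals[i, j] = (1 + exceed) / (1 + r)
    return pvals


def te_connectivity(scan: ScanSeries, lag: int = DEFAULT_LAG, scale: float = DEFAULT_SCALE,
                    n_permutations: int = 100, seed=None,
                    standardize_first: bool = True, future_mode: str = "circular"
                    ) -> ConnectivityResult:
    """TE result (values + shuffle p-values) for one scan."""
    scan.require_length(max(lag + 2, 64))
    values = te_matrix(scan.matrix, lag=lag, scale=scale,
                       standardize_first=standardize_first, future_mode=future_mode)
    p = te_shuffle_pvalues(scan.matrix, lag=lag, scale=scale,
                           n_permutations=n_permutations, seed=seed,
                           standardize_first=standardize_first,
                           future_mode=future_mode, observed=values)
    return ConnectivityResult(
        "TE", values, p, scan.roi_names,
        params={"lag": lag, "discretization_scale": scale,
                "n_permutations": n_permutations, "seed": None if seed is None else int(seed),
                "future_mode": future_mode, "log_base": 2},
        subject_id=scan.subject_id, condition=scan.condition)


def lag_scan(target: np.ndarray, source: np.ndarray, lags,
             scale: float = DEFAULT_SCALE, **kw) -> pd.DataFrame:
    """TE as a function of lag, for choosing/justifying the analysis lag.

    Reported, never auto-selected: the pipeline always runs at an explicit,
    fixed lag.
    """
    rows = [{"lag": int(lg),
             "te_bits": transfer_entropy(target, source, lag=int(lg), scale=scale, **kw)}
            for lg in lags]
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# head-motion artifact check
# --------------------------------------------------------------------------

def motion_augmented_pc(scan: ScanSeries, translation_modulus: np.ndarray,
                        rotation_modulus: np.ndarray, ridge: float = DEFAULT_RIDGE
                        ) -> tuple[np.ndarray, np.ndarray, float]:
    """PC with and without motion-regressor augmentation.

    The N-region PC matrix is recomputed after appending the translational
    and rotational motion moduli as two extra variables; the N x N
    sub-block of the augmented PC is returned alongside the original and
    their element-wise maximum absolute difference.  Motion-free data
    should show essentially no change.
    """
    t_mod = np.asarray(translation_modulus, dtype=float)
    r_mod = np.asarray(rotation_modulus, dtype=float)
    t_len = scan.n_timepoints
    if t_mod.shape != (t_len,) or r_mod.shape != (t_len,):
        raise ValueError("motion regressors must match the scan length")
    for name, reg in (("translation", t_mod), ("rotation", r_mod)):
        if reg.std() == 0:
            raise ValueError(f"{name} modulus regressor has zero variance")
    pc_orig = partial_correlation(correlation_matrix(scan.matrix), ridge=ridge)
    aug = np.column_stack([scan.matrix, t_mod, r_mod])
    pc_aug = partial_correlation(correlation_matrix(aug), ridge=ridge)
    n = scan.n_rois
    sub = pc_aug[:n, :n]
    off = ~np.eye(n, dtype=bool)
    max_delta = float(np.nanmax(np.abs(pc_orig - sub)[off]))
    return pc_orig, sub, max_delta
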