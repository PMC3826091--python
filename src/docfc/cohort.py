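"""Synthetic resting-state cohort with known connectivity ground truth.

No public dataset accompanies the analysis this package implements, so the
study conditions are emulated by a generative model with controllable
ground truth:

* a bilateral atlas (mirrored centroids, right-skewed region sizes around
  ~150 voxels, every region paired with a contralateral homologue);
* per-region BOLD-like series from a lagged linear (VAR-style) recursion:
  an AR(1) own-history term, a shared innovation per homologue pair whose
  weight sets the *instantaneous homotopic coupling* (what partial
  correlation detects), directed lagged inputs over sampled edges (what
  transfer entropy detects), and Gaussian innovations; the series are then
  linearly detrended and band-passed to 0.01-0.08 Hz;
* two conditions: "control" with strong homotopic coupling and dense
  directed edges, and "doc" (patient-like) with weak homotopic coupling
  and sparse edges.  Each patient additionally gets a severity factor
  u ~ U(0.3, 1): it scales the homotopic coupling, each planted edge is
  retained with probability u, and CRS-R subscale scores are drawn to
  increase with u — so score-connectivity correlations are recoverable
  by construction.

All randomness flows from a single cohort seed through a documented
``numpy.random.SeedSequence`` splitting scheme, so cohorts regenerate
bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import ROIAtlas
from .preprocess import CRSR_SUBSCALES, ScanSeries, detrend_bandpass

CONDITIONS = ("control", "doc")


@dataclass
class CohortConfig:
    """Generator parameters; defaults define the emulated study conditions."""

    n_rois: int = 90
    n_timepoints: int = 215          # 220 volumes minus 5 dummy scans
    tr: float = 2.0                  # seconds
    band: tuple[float, float] = (0.01, 0.08)   # Hz
    n_subjects_per_group: int = 15
    seed: int = 0
    # dynamics
    ar_coeff: float = 0.3
    noise_sd: float = 1.0
    burn_in: int = 200
    # homotopic (instantaneous shared-innovation) coupling per condition
    homotopic_coupling: dict = field(
        default_factory=lambda: {"control": 0.8, "doc": 0.3})
    # directed lagged edges: density over eligible ordered pairs, per condition
    edge_density: dict = field(default_factory=lambda: {"control": 0.10, "doc": 0.05})
    edge_weight: float = 3.0
    edge_lag: int = 10               # matches the analysis lag
    # optional explicit edge lists per condition: [(source, target, lag, weight), ...]
    directed_edges: dict | None = None
    # DOC severity factor range: scales the homotopic coupling and the
    # retention probability of the condition's directed edges per patient
    severity_range: tuple[float, float] = (0.3, 1.0)

    def validate(self) -> None:
        if self.n_rois % 2 or self.n_rois < 4:
            raise ValueError("n_rois must be even and >= 4")
        if self.edge_lag < 1:
            raise ValueError("edge lags must be >= 1")
        for cond in CONDITIONS:
            if cond not in self.homotopic_coupling or cond not in self.edge_density:
                raise ValueError(f"missing condition {cond!r} in coupling config")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """What the generator actually planted, for parameter-recovery checks."""

    directed_edges: dict            # condition -> list of (source, target, lag, weight)
    homotopic_coupling: dict        # condition -> weight
    severity: dict                  # subject_id -> severity factor (controls: 1.0)
    condition: dict                 # subject_id -> condition label
    config: dict
    subject_edges: dict = field(default_factory=dict)  # subject_id -> retained edges

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


# --------------------------------------------------------------------------
# atlas generation
# --------------------------------------------------------------------------

def generate_atlas(n_rois: int, seed: int) -> ROIAtlas:
    """Bilateral synthetic atlas: mirrored centroids plus jitter.

    Region sizes are drawn from a right-skewed Gamma distribution with mean
    ~150 voxels, clipped at 600, emulating the size spread of a standard
    90-area parcellation.  Names follow ``AREA_<k>_L`` / ``AREA_<k>_R``.
    """
    if n_rois % 2 or n_rois < 4:
        raise ValueError("n_rois must be even and >= 4")
    rng = np.random.default_rng(seed)
    n_pairs = n_rois // 2
    base = np.column_stack([
        rng.uniform(8.0, 70.0, n_pairs),      # |x|, distance from midline
        rng.uniform(-90.0, 60.0, n_pairs),    # y
        rng.uniform(-45.0, 75.0, n_pairs),    # z
    ])
    jitter = rng.normal(0.0, 2.0, size=(n_pairs, 2, 3))
    left = base.copy()
    left[:, 0] *= -1.0
    centroids = np.empty((n_rois, 3))
    centroids[0::2] = left + jitter[:, 0]
    centroids[1::2] = base + jitter[:, 1]
    sizes = np.clip(rng.gamma(shape=4.0, scale=37.5, size=n_pairs), 20, 600)
    sizes = np.repeat(np.round(sizes).astype(int), 2)
    names, hemi, homol = [], [], []
    for p in range(n_pairs):
        names += [f"AREA_{p + 1:03d}_L", f"AREA_{p + 1:03d}_R"]
        hemi += ["L", "R"]
        homol += [2 * p + 1, 2 * p]
    return ROIAtlas(names=tuple(names), hemisphere=np.array(hemi),
                    homologue=np.array(homol), centroids=centroids,
                    size_voxels=sizes)


# --------------------------------------------------------------------------
# scan simulation
# --------------------------------------------------------------------------

def sample_directed_edges(atlas: ROIAtlas, config: CohortConfig, condition: str,
                          rng: np.random.Generator) -> list[tuple[int, int, int, float]]:
    """Sample the condition's directed edge set.

    Eligible pairs are ordered non-homologue pairs with source index below
    target index, so the lagged directed structure is acyclic: an acyclic
    lagged system is stable for any edge weight (no feedback loops to
    amplify), which decouples edge strength from stability.  The homotopic
    (instantaneous) structure is kept separate by excluding homologue
    pairs.  ``edge_density`` gives the sampled fraction of eligible pairs;
    every edge gets the configured lag and weight.  Each target receives at
    most one incoming edge, so a driven region is dominated by a single
    source rather than a washed-out mixture.
    """
    n = atlas.n_rois
    eligible = [(j, i) for i in range(n) for j in range(n)
                if j < i and atlas.homologue[j] != i]
    k = int(round(config.edge_density[condition] * len(eligible)))
    if k <= 0:
        return []
    order = rng.permutation(len(eligible))
    taken: list[tuple[int, int]] = []
    used_targets: set[int] = set()
    for q in order:
        src, tgt = eligible[q]
        if tgt in used_targets:
            continue
        taken.append((src, tgt))
        used_targets.add(tgt)
        if len(taken) == k:
            break
    return [(src, tgt, config.edge_lag, config.edge_weight)
            for src, tgt in sorted(taken)]


def _edges_for(atlas: ROIAtlas, config: CohortConfig, condition: str
               ) -> list[tuple[int, int, int, float]]:
    if config.directed_edges is not None:
        return [tuple(e) for e in config.directed_edges[condition]]
    edge_ss = np.random.SeedSequence([int(config.seed), 9001, CONDITIONS.index(condition)])
    return sample_directed_edges(atlas, config, condition,
                                 np.random.default_rng(edge_ss))


def spectral_radius(atlas: ROIAtlas, config: CohortConfig,
                    edges, coupling_scale: float = 1.0) -> float:
    """Spectral radius of the companion matrix of the lagged recursion."""
    n = atlas.n_rois
    max_lag = max([1] + [e[2] for e in edges])
    lag_mats = np.zeros((max_lag, n, n))
    lag_mats[0] += np.eye(n) * config.ar_coeff
    for src, tgt, lg, w in edges:
        lag_mats[lg - 1, tgt, src] += w
    comp = np.zeros((n * max_lag, n * max_lag))
    for lg in range(max_lag):
        comp[:n, lg * n:(lg + 1) * n] = lag_mats[lg]
    if max_lag > 1:
        comp[n:, :-n] = np.eye(n * (max_lag - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def simulate_scan(atlas: ROIAtlas, config: CohortConfig, condition: str, seed,
                  *, directed_edges=None, coupling_scale: float = 1.0,
                  subject_id: str | None = None, crsr: dict | None = None,
                  months_since_injury: float | None = None,
                  check_stability: bool = True) -> ScanSeries:
    """Simulate one scan of the given condition.

    ``coupling_scale`` multiplies the homotopic (shared-innovation) weight
    — the per-patient severity factor.  Directed-edge strength is carried
    entirely by the edge list, which is sampled deterministically from the
    config seed unless given explicitly; severity acts on edges through
    the per-patient edge retention applied by :func:`generate_cohort`.
    """
    config.validate()
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    n = atlas.n_rois
    edges = directed_edges if directed_edges is not None else _edges_for(atlas, config, condition)
    if check_stability:
        rho = spectral_radius(atlas, config, edges)
        if rho >= 1.0:
            raise ValueError(f"unstable coupling configuration (spectral radius {rho:.3f})")
    rng = np.random.default_rng(seed)
    t_total = config.n_timepoints + config.burn_in
    max_lag = max([1] + [e[2] for e in edges])
    h_w = config.homotopic_coupling[condition] * coupling_scale
    if not (0.0 <= h_w < 1.0):
        raise ValueError("homotopic coupling must lie in [0, 1) (correlation scale)")
    # innovations: private noise + shared per-homologue-pair component whose
    # amplitude sqrt(w/(1-w)) makes the innovation correlation equal w
    drive = rng.normal(0.0, config.noise_sd, size=(t_total, n))
    pair_members = [(i, int(atlas.homologue[i])) for i in range(n)
                    if atlas.homologue[i] > i]
    if pair_members and h_w:
        amp = config.noise_sd * np.sqrt(h_w / (1.0 - h_w))
        shared = rng.normal(0.0, 1.0, size=(t_total, len(pair_members)))
        for p, (a, b) in enumerate(pair_members):
            drive[:, a] += amp * shared[:, p]
            drive[:, b] += amp * shared[:, p]
    lag_weights: dict[int, np.ndarray] = {}
    for src, tgt, lg, w in edges:
        lag_weights.setdefault(lg, np.zeros((n, n)))[tgt, src] += w
    x = np.zeros((t_total + max_lag, n))
    x[:max_lag] = rng.normal(0.0, config.noise_sd, size=(max_lag, n))
    for t in range(max_lag, t_total + max_lag):
        row = config.ar_coeff * x[t - 1] + drive[t - max_lag]
        for lg, w_mat in lag_weights.items():
            row += w_mat @ x[t - lg]
        x[t] = row
    series = x[max_lag + config.burn_in:]
    series = detrend_bandpass(series, config.tr, *config.band)
    return ScanSeries(subject_id=subject_id or f"{condition}_s{seed}",
                      condition=condition, matrix=series, tr=config.tr,
                      roi_names=atlas.names, crsr=crsr,
                      months_since_injury=months_since_injury)


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

def _crsr_scores(severity: float, lo: float, hi: float,
                 rng: np.random.Generator) -> dict[str, int]:
    """CRS-R subscales increasing with the severity factor (higher = better).

    Each subscale is ``round(max * p)`` with p an affine map of the
    severity factor into [0.05, 0.95] plus a small Gaussian jitter, then
    clipped to the subscale range; the total is the sum, hence always in
    0..23.  The jitter keeps scores stochastic while preserving a tight
    monotone link between severity and the total score.
    """
    p = 0.05 + 0.9 * (severity - lo) / (hi - lo)
    scores = {}
    for name, mx in CRSR_SUBSCALES.items():
        val = int(round(mx * float(np.clip(p + rng.normal(0.0, 0.08), 0.0, 1.0))))
        scores[name] = int(np.clip(val, 0, mx))
    scores["total"] = int(sum(scores.values()))
    return scores


def generate_cohort(config: CohortConfig, atlas: ROIAtlas | None = None
                    ) -> tuple[list[ScanSeries], GroundTruth, pd.DataFrame]:
    """Generate the full two-condition cohort.

    Returns the scans, the planted ground truth, and a subject manifest
    (condition, severity, CRS-R subscales for patients, months since
    injury).  Reproducible bit-for-bit from (config, seed).
    """
    config.validate()
    ss = np.random.SeedSequence(int(config.seed))
    atlas_seed, *subject_seeds = ss.generate_state(
        1 + 2 * config.n_subjects_per_group + 1)
    if atlas is None:
        atlas = generate_atlas(config.n_rois, int(atlas_seed) % (2 ** 31))
    meta_rng = np.random.default_rng(int(subject_seeds[-1]))
    edges = {cond: _edges_for(atlas, config, cond) for cond in CONDITIONS}
    lo, hi = config.severity_range
    scans: list[ScanSeries] = []
    severity: dict[str, float] = {}
    cond_of: dict[str, str] = {}
    subject_edges: dict[str, list] = {}
    rows = []
    k = 0
    for cond in CONDITIONS:
        for s in range(config.n_subjects_per_group):
            sid = f"{cond}_{s + 1:02d}"
            if cond == "doc":
                # severity u: scales homotopic coupling, and each planted
                # edge survives with probability u (sicker patients retain
                # fewer directed influences)
                u = float(meta_rng.uniform(lo, hi))
                crsr = _crsr_scores(u, lo, hi, meta_rng)
                months = float(meta_rng.integers(2, 7))
                my_edges = [e for e in edges[cond] if meta_rng.random() < u]
            else:
                u, crsr, months = 1.0, None, None
                my_edges = edges[cond]
            scan = simulate_scan(atlas, config, cond, int(subject_seeds[k]),
                                 directed_edges=my_edges, coupling_scale=u,
                                 subject_id=sid, crsr=crsr,
                                 months_since_injury=months,
                                 check_stability=(s == 0))
            k += 1
            scans.append(scan)
            severity[sid] = u
            cond_of[sid] = cond
            subject_edges[sid] = my_edges
            row = {"subject_id": sid, "condition": cond, "severity": u,
                   "months_since_injury": months}
            for name in CRSR_SUBSCALES:
                row[name] = crsr[name] if crsr else np.nan
            row["crsr_total"] = crsr["total"] if crsr else np.nan
            rows.append(row)
    truth = GroundTruth(directed_edges=edges,
                        homotopic_coupling=dict(config.homotopic_coupling),
                        severity=severity, condition=cond_of,
                        config=config.to_dict(), subject_edges=subject_edges)
    return scans, truth, pd.DataFrame(rows)


def write_cohort(out_dir, scans: list[ScanSeries], truth: GroundTruth,
                 manifest: pd.DataFrame, atlas: ROIAtlas) -> None:
    """Write scans (one TSV each), manifest, atlas sidecar and ground truth."""
    out = Path(out_dir)
    (out / "scans").mkdir(parents=True, exist_ok=True)
    for scan in scans:
        scan.to_tsv(out / "scans" / f"{scan.subject_id}.tsv")
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False, float_format="%.6g")
    atlas.to_tsv(out / "atlas.tsv")
    truth.to_json(out / "ground_truth.json")


def read_cohort(in_dir, tr: float | None = None
                ) -> tuple[list[ScanSeries], pd.DataFrame]:
    """Load scans + manifest written by :func:`write_cohort`."""
    from .preprocess import read_scan
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.tsv", sep="\t")
    truth_path = in_dir / "ground_truth.json"
    if tr is None:
        tr = 2.0
        if truth_path.exists():
            tr = float(json.loads(truth_path.read_text())["config"]["tr"])
    scans = []
    for _, row in manifest.iterrows():
        crsr = None
        if row["condition"] == "doc" and not pd.isna(row.get("crsr_total", np.nan)):
            crsr = {name: int(row[name]) for name in CRSR_SUBSCALES}
            crsr["total"] = int(row["crsr_total"])
        months = row.get("months_since_injury", np.nan)
        scans.append(read_scan(
            in_dir / "scans" / f"{row['subject_id']}.tsv",
            subject_id=row["subject_id"], condition=row["condition"], tr=tr,
            crsr=crsr, months_since_injury=None if pd.isna(months) else float(months)))
    return scans, manifest
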