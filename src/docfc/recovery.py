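"""Parameter-recovery and calibration experiments on synthetic cohorts.

These drivers answer the validation questions the pipeline is built
around: given cohorts generated with *known* reduced homotopic coupling
and sparser directed edges in the patient-like condition, does the
pipeline recover the expected pattern —

* homologue inter-hemispheric (HIH) partial correlation higher in
  controls, with a significant Bonferroni post-hoc difference;
* left intra-hemispheric (LL) and non-homologue inter-hemispheric (LR)
  transfer entropy higher in controls (category means over pairs
  surviving the p <= 0.1 threshold);
* more significant LL TE links (link density) in controls —

and is the TE shuffle test calibrated (rejection rate ~ alpha) on
independent channels?

The default problem size (20 bilateral regions, 15 subjects per group,
215 time points, 29-permutation nulls) keeps a 20-seed study tractable on
a laptop while preserving the statistical structure of the full 90-region
setting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import CohortConfig, generate_atlas, generate_cohort
from .connectivity import pc_connectivity, te_connectivity, te_matrix, te_shuffle_pvalues
from .groupstats import link_density, posthoc_bonferroni, summarize_cohort
from .pipeline import _atlas_seed

GROUPS = ("control", "doc")


def recovery_trial(seed: int, n_rois: int = 20, n_subjects_per_group: int = 15,
                   n_permutations: int = 29, alpha: float = 0.1,
                   lag: int = 10, scale: float = 3.0) -> dict:
    """Run the two-group contrast on one synthetic cohort.

    Returns the group differences (control minus patient-like) of the
    thresholded LL/LR TE category means and the mean LL link density, and
    whether the HIH PC post-hoc difference is significant in the control
    direction.
    """
    config = CohortConfig(n_rois=n_rois, seed=int(seed),
                          n_subjects_per_group=n_subjects_per_group)
    scans, truth, manifest = generate_cohort(config)
    atlas = generate_atlas(n_rois, _atlas_seed(config))
    pc_results = [pc_connectivity(s) for s in scans]
    te_results = [te_connectivity(s, lag=lag, scale=scale,
                                  n_permutations=n_permutations,
                                  seed=(int(seed) * 1000 + k) % (2 ** 31))
                  for k, s in enumerate(scans)]
    pc_summary = summarize_cohort(pc_results, atlas, alpha=alpha)
    te_summary = summarize_cohort(te_results, atlas, alpha=alpha)
    posthoc = posthoc_bonferroni(pc_summary, GROUPS).set_index("category")
    hih = posthoc.loc["HIH"]
    te_means = (te_summary[te_summary.category.isin(["LL", "LR"])]
                .groupby(["category", "condition"], observed=True)["mean_value"].mean())
    density = {g: float(np.mean([link_density(r, atlas, "LL", alpha=alpha)
                                 for r in te_results if r.condition == g]))
               for g in GROUPS}
    return {
        "seed": int(seed),
        "hih_pc_control": float(hih.mean_1),
        "hih_pc_doc": float(hih.mean_2),
        "hih_posthoc_p": float(hih.p_bonferroni),
        "hih_pc_significant": bool(hih.mean_1 > hih.mean_2
                                   and hih.p_bonferroni < 0.05),
        "ll_te_diff": float(te_means["LL", "control"] - te_means["LL", "doc"]),
        "lr_te_diff": float(te_means["LR", "control"] - te_means["LR", "doc"]),
        "ll_link_density_control": density["control"],
        "ll_link_density_doc": density["doc"],
        "ll_link_density_diff": density["control"] - density["doc"],
    }


def recovery_study(n_seeds: int = 20, base_seed: int = 0, **trial_kw) -> pd.DataFrame:
    """Repeat :func:`recovery_trial` over independent cohort seeds."""
    rows = [recovery_trial((base_seed * 10007 + k) % (2 ** 31), **trial_kw)
            for k in range(n_seeds)]
    return pd.DataFrame(rows)


def recovery_fractions(study: pd.DataFrame) -> dict:
    """Fraction of seeds recovering each expected group contrast."""
    n = len(study)
    return {
        "hih_pc_significant": float(study.hih_pc_significant.mean()),
        "ll_te_control_higher": float((study.ll_te_diff > 0).mean()),
        "lr_te_control_higher": float((study.lr_te_diff > 0).mean()),
        "ll_link_density_control_higher": float((study.ll_link_density_diff > 0).mean()),
        "n_seeds": n,
    }


def crsr_recovery_trial(seed: int, n_rois: int = 20, n_doc: int = 12,
                        n_permutations: int = 29, alpha: float = 0.1) -> dict:
    """Correlate per-patient connectivity readouts with CRS-R totals.

    Only the patient-like arm is analysed (n_doc scans).  Reports the
    Pearson r of the thresholded HIH PC mean, the thresholded LL TE mean
    and the LL link density against the total CRS-R score.  The generator
    plants a tight monotone severity -> CRS-R link, so these correlations
    are positive in expectation; their magnitude is limited by the
    per-scan measurement noise of the estimators at T = 215.
    """
    from scipy.stats import pearsonr

    config = CohortConfig(n_rois=n_rois, seed=int(seed),
                          n_subjects_per_group=n_doc)
    scans, truth, manifest = generate_cohort(config)
    atlas = generate_atlas(n_rois, _atlas_seed(config))
    doc = [s for s in scans if s.condition == "doc"]
    te_results = [te_connectivity(s, n_permutations=n_permutations,
                                  seed=(int(seed) * 977 + k) % (2 ** 31))
                  for k, s in enumerate(doc)]
    pc_results = [pc_connectivity(s) for s in doc]
    te_summary = summarize_cohort(te_results, atlas, alpha=alpha)
    pc_summary = summarize_cohort(pc_results, atlas, alpha=alpha)
    meta = manifest[manifest.condition == "doc"].set_index("subject_id")
    ll_te = te_summary[te_summary.category == "LL"].set_index("subject_id")["mean_value"]
    hih_pc = pc_summary[pc_summary.category == "HIH"].set_index("subject_id")["mean_value"]
    density = pd.Series({r.subject_id: link_density(r, atlas, "LL", alpha=alpha)
                         for r in te_results})
    out = {"seed": int(seed), "n_doc": n_doc}
    for name, series in (("hih_pc", hih_pc), ("ll_te", ll_te),
                         ("ll_link_density", density.astype(float))):
        joined = pd.concat([series, meta["crsr_total"]], axis=1).dropna()
        out[f"r_{name}"] = (float(pearsonr(joined.iloc[:, 0], joined.iloc[:, 1])[0])
                            if joined.iloc[:, 0].nunique() > 1 else np.nan)
    out["r_severity_crsr"] = float(pearsonr(meta["severity"], meta["crsr_total"])[0])
    return out


def null_calibration(seed: int, n_channels: int = 9, n_scans: int = 8,
                     n_timepoints: int = 215, n_permutations: int = 99,
                     alpha: float = 0.1, lag: int = 10, scale: float = 3.0) -> dict:
    """TE shuffle-test rejection rate on independent white-noise channels.

    All channels are i.i.d. Gaussian, so every ordered pair is null and
    the permutation test should reject a fraction ~ alpha of the ordered
    pairs.  The pairs are spread over several small independent scans
    (``n_scans`` x ``n_channels*(n_channels-1)`` pairs) so that shared
    target permutations within a scan contribute little dependence.
    """
    rng = np.random.default_rng(seed)
    off = ~np.eye(n_channels, dtype=bool)
    hits = total = 0
    for k in range(n_scans):
        x = rng.normal(size=(n_timepoints, n_channels))
        observed = te_matrix(x, lag=lag, scale=scale)
        pvals = te_shuffle_pvalues(x, lag=lag, scale=scale,
                                   n_permutations=n_permutations,
                                   seed=int(seed) + 17 * k + 1, observed=observed)
        hits += int((pvals[off] <= alpha).sum())
        total += int(off.sum())
    rate = hits / total
    n_pairs = total
    half_width = 1.96 * np.sqrt(alpha * (1 - alpha) / n_pairs)
    return {"rejection_rate": rate, "alpha": alpha, "n_pairs": n_pairs,
            "ci_low": alpha - half_width, "ci_high": alpha + half_width,
            "within_ci": bool(alpha - half_width <= rate <= alpha + half_width)}
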