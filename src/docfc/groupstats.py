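"""Thresholding, category summaries and group-comparison statistics.

Per scan, the connectivity matrices are thresholded at a significance
level (p <= alpha, default 0.1) and averaged within each hemispheric pair
category; the per-scan category means then enter a two-way ANOVA
(group x category, Type II sums of squares), Bonferroni-corrected post-hoc
two-sample t-tests per category, and Kruskal-Wallis tests as a
distribution-free check.  Category means where *every* pair is rejected
propagate as missing values, never as zeros.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .atlas import ROIAtlas, TOTAL
from .connectivity import ConnectivityResult
from .preprocess import CRSR_SUBSCALES

DEFAULT_ALPHA = 0.1


def threshold_and_summarize(result: ConnectivityResult, atlas: ROIAtlas,
                            alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Per-category mean over significant pairs plus rejected fraction.

    Pairs with p > alpha are excluded from the mean; ``rejected_fraction``
    is the fraction excluded.  One row per category (including TOTAL).
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    values, pvals = result.values, result.pvalues
    if pvals is None or values.shape != pvals.shape:
        raise ValueError("result must carry aligned value and p-value matrices")
    masks = atlas.category_masks(directed=result.directed)
    rows = []
    for cat, mask in masks.items():
        v = values[mask]
        p = pvals[mask]
        keep = p <= alpha
        rows.append({
            "subject_id": result.subject_id,
            "condition": result.condition,
            "measure": result.measure,
            "category": cat,
            "mean_value": float(v[keep].mean()) if keep.any() else np.nan,
            "rejected_fraction": float(1.0 - keep.mean()) if keep.size else np.nan,
            "n_pairs": int(keep.size),
            "n_significant": int(keep.sum()),
            "alpha": alpha,
        })
    return pd.DataFrame(rows)


def summarize_cohort(results: list[ConnectivityResult], atlas: ROIAtlas,
                     alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Stack :func:`threshold_and_summarize` over a cohort of results."""
    return pd.concat(
        [threshold_and_summarize(r, atlas, alpha) for r in results],
        ignore_index=True)


def _two_group_frame(summaries: pd.DataFrame, groups: tuple[str, str],
                     value_col: str = "mean_value") -> pd.DataFrame:
    df = summaries[summaries["condition"].isin(groups)].copy()
    df = df[df["category"] != TOTAL].dropna(subset=[value_col])
    if df.empty:
        raise ValueError("no usable category means for the requested groups")
    return df


def two_way_anova(summaries: pd.DataFrame, groups: tuple[str, str],
                  value_col: str = "mean_value") -> pd.DataFrame:
    """Two-way ANOVA (group x category) on per-scan category means.

    Type II sums of squares, which on a balanced design reduce to the
    classical decomposition.  Returns a table with effect, sum_sq, df, F, p.
    """
    df = _two_group_frame(summaries, groups, value_col)
    for g in groups:
        if df.loc[df["condition"] == g, "subject_id"].nunique() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    if df["category"].nunique() < 2:
        raise ValueError("need at least 2 categories")
    model = smf.ols(f"{value_col} ~ C(condition) * C(category)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2).reset_index().rename(
        columns={"index": "effect", "PR(>F)": "p"})
    table["effect"] = table["effect"].replace({
        "C(condition)": "group", "C(category)": "category",
        "C(condition):C(category)": "group:category", "Residual": "residual"})
    return table


def posthoc_bonferroni(summaries: pd.DataFrame, groups: tuple[str, str],
                       categories: list[str] | None = None,
                       value_col: str = "mean_value") -> pd.DataFrame:
    """Per-category two-sample t-tests with Bonferroni correction.

    The raw p of each category's t-test is multiplied by the number of
    categories tested, capped at 1.
    """
    df = _two_group_frame(summaries, groups, value_col)
    cats = categories or sorted(df["category"].unique())
    m = len(cats)
    rows = []
    for cat in cats:
        a = df.loc[(df["category"] == cat) & (df["condition"] == groups[0]), value_col]
        b = df.loc[(df["category"] == cat) & (df["condition"] == groups[1]), value_col]
        if len(a) < 2 or len(b) < 2:
            rows.append({"category": cat, "mean_1": a.mean(), "mean_2": b.mean(),
                         "t": np.nan, "p_raw": np.nan, "p_bonferroni": np.nan})
            continue
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            raise ValueError(f"zero within-group variance in category {cat!r}")
        t, p = stats.ttest_ind(a, b)
        rows.append({"category": cat, "mean_1": float(a.mean()),
                     "mean_2": float(b.mean()), "t": float(t),
                     "p_raw": float(p), "p_bonferroni": float(min(1.0, m * p))})
    return pd.DataFrame(rows)


def kruskal_wallis_by_category(summaries: pd.DataFrame, groups: tuple[str, str],
                               value_col: str = "mean_value") -> pd.DataFrame:
    """Kruskal-Wallis H (rank-based, tie-corrected) per category."""
    df = _two_group_frame(summaries, groups, value_col)
    rows = []
    for cat in sorted(df["category"].unique()):
        a = df.loc[(df["category"] == cat) & (df["condition"] == groups[0]), value_col]
        b = df.loc[(df["category"] == cat) & (df["condition"] == groups[1]), value_col]
        if len(a) < 2 or len(b) < 2:
            rows.append({"category": cat, "H": np.nan, "p": np.nan})
            continue
        if np.ptp(np.concatenate([a, b])) == 0:
            raise ValueError(f"all values tied in category {cat!r}")
        h, p = stats.kruskal(a, b)
        rows.append({"category": cat, "H": float(h), "p": float(p)})
    return pd.DataFrame(rows)


def link_density(result: ConnectivityResult, atlas: ROIAtlas, category: str,
                 alpha: float = DEFAULT_ALPHA,
                 magnitude_threshold: float | None = None) -> int:
    """Number of significant links in a category.

    Counts (ordered, for directed measures) pairs with p <= alpha and,
    if given, value > magnitude_threshold.
    """
    masks = atlas.category_masks(directed=result.directed)
    if category not in masks:
        raise KeyError(f"unknown category {category!r} for measure {result.measure}")
    mask = masks[category]
    keep = (result.pvalues[mask] <= alpha)
    if magnitude_threshold is not None:
        keep &= result.values[mask] > magnitude_threshold
    return int(keep.sum())


def homologue_pair_values(result: ConnectivityResult, atlas: ROIAtlas) -> pd.DataFrame:
    """Per homologue pair: the (symmetric) value and the pair's centroid distance."""
    rows = []
    dist = atlas.distance_matrix()
    for i in range(atlas.n_rois):
        j = int(atlas.homologue[i])
        if j <= i:
            continue
        v = result.values[i, j]
        if result.directed:
            v = 0.5 * (result.values[i, j] + result.values[j, i])
        rows.append({"subject_id": result.subject_id, "condition": result.condition,
                     "roi_i": i, "roi_j": j, "value": float(v),
                     "distance_mm": float(dist[i, j])})
    return pd.DataFrame(rows)


def distance_stratified_compare(pair_values: pd.DataFrame, groups: tuple[str, str],
                                bin_edges_mm: tuple[float, ...] = (20.0, 40.0)
                                ) -> pd.DataFrame:
    """Group comparison of pair values within centroid-distance bins.

    Default bins: < 20 mm, 20-40 mm, > 40 mm.  Per bin, a two-sample
    t-test between groups over the pooled pair values; empty bins are
    reported with missing statistics rather than raised.
    """
    edges = [0.0, *bin_edges_mm, np.inf]
    labels = [f"<{bin_edges_mm[0]:g}mm"] + [
        f"{a:g}-{b:g}mm" for a, b in zip(bin_edges_mm[:-1], bin_edges_mm[1:])
    ] + [f">{bin_edges_mm[-1]:g}mm"]
    df = pair_values[pair_values["condition"].isin(groups)].copy()
    df["bin"] = pd.cut(df["distance_mm"], bins=edges, labels=labels)
    rows = []
    for label in labels:
        a = df.loc[(df["bin"] == label) & (df["condition"] == groups[0]), "value"]
        b = df.loc[(df["bin"] == label) & (df["condition"] == groups[1]), "value"]
        if len(a) < 2 or len(b) < 2:
            rows.append({"bin": label, "n_1": len(a), "n_2": len(b),
                         "mean_1": a.mean() if len(a) else np.nan,
                         "mean_2": b.mean() if len(b) else np.nan,
                         "t": np.nan, "p": np.nan})
            continue
        t, p = stats.ttest_ind(a, b)
        rows.append({"bin": label, "n_1": len(a), "n_2": len(b),
                     "mean_1": float(a.mean()), "mean_2": float(b.mean()),
                     "t": float(t), "p": float(p)})
    return pd.DataFrame(rows)


def area_mean_connectivity(result: ConnectivityResult,
                           alpha: float = 1.0) -> np.ndarray:
    """Per-area mean connectivity over significant off-diagonal partners."""
    v = result.values.copy()
    if result.pvalues is not None and alpha < 1.0:
        v[result.pvalues > alpha] = np.nan
    with np.errstate(invalid="ignore"):
        row = np.nanmean(v, axis=1)
        col = np.nanmean(v, axis=0)
    return np.nanmean(np.column_stack([row, col]), axis=1)


def decorrelation_index(mean_control: np.ndarray, mean_patient: np.ndarray,
                        names: list[str] | None = None, top_k: int = 5
                        ) -> pd.DataFrame:
    """Per-area relative connectivity loss, (control - patient) / control.

    Areas with zero control mean are flagged (index missing) and excluded
    from the ranking.  ``rank_top`` marks the ``top_k`` largest indices
    (most impaired areas), ``rank_bottom`` the smallest.
    """
    c = np.asarray(mean_control, dtype=float)
    p = np.asarray(mean_patient, dtype=float)
    if c.shape != p.shape:
        raise ValueError("control and patient vectors must align")
    with np.errstate(divide="ignore", invalid="ignore"):
        idx = np.where(c != 0, (c - p) / c, np.nan)
    df = pd.DataFrame({
        "area": names if names is not None else [f"roi_{k}" for k in range(c.size)],
        "mean_control": c, "mean_patient": p, "decorrelation_index": idx,
        "flagged_zero_control": c == 0,
    })
    order = df["decorrelation_index"].rank(ascending=False, method="first")
    valid = df["decorrelation_index"].notna()
    df["rank_top"] = valid & (order <= top_k)
    df["rank_bottom"] = valid & (order > valid.sum() - top_k)
    return df


def crsr_correlation(measures: pd.DataFrame, manifest: pd.DataFrame,
                     measure_cols: list[str] | None = None,
                     method: str = "pearson") -> pd.DataFrame:
    """Correlate per-scan connectivity measures with CRS-R scores.

    ``measures`` must carry ``subject_id`` plus one column per measure
    (e.g. the HIH PC mean, the LL TE mean); scores are the six CRS-R
    subscales, the total, and months since injury from the manifest.
    Constant score vectors yield missing correlations.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    merged = measures.merge(manifest, on="subject_id", how="inner")
    score_cols = [*CRSR_SUBSCALES, "crsr_total", "months_since_injury"]
    score_cols = [c for c in score_cols if c in merged.columns]
    if measure_cols is None:
        measure_cols = [c for c in measures.columns if c != "subject_id"]
    merged = merged.dropna(subset=["crsr_total"])
    if len(merged) < 3:
        raise ValueError("need at least 3 scans with CRS-R scores")
    corr_fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    rows = []
    for mc in measure_cols:
        for sc in score_cols:
            sub = merged[[mc, sc]].dropna()
            if len(sub) < 3 or sub[sc].nunique() < 2 or sub[mc].nunique() < 2:
                rows.append({"measure": mc, "score": sc, "r": np.nan,
                             "p": np.nan, "n": len(sub)})
                continue
            r, p = corr_fn(sub[mc], sub[sc])
            rows.append({"measure": mc, "score": sc, "r": float(r),
                         "p": float(p), "n": len(sub)})
    return pd.DataFrame(rows)


def format_group_table(summaries: pd.DataFrame, groups: tuple[str, str],
                       posthoc: pd.DataFrame | None = None,
                       alpha: float = 0.05) -> str:
    """Readable mean +/- SD table per group x category with significance marks."""
    df = summaries[summaries["condition"].isin(groups)]
    lines = [f"{'category':<10}" + "".join(f"{g:>22}" for g in groups) + "   sig"]
    sig = {}
    if posthoc is not None:
        sig = dict(zip(posthoc["category"], posthoc["p_bonferroni"]))
    for cat in df["category"].unique():
        cells = []
        for g in groups:
            vals = df.loc[(df["category"] == cat) & (df["condition"] == g), "mean_value"]
            cells.append(f"{vals.mean():.4f} +/- {vals.std(ddof=1):.4f}")
        mark = "*" if sig.get(cat, 1.0) <= alpha else ""
        lines.append(f"{cat:<10}" + "".join(f"{c:>22}" for c in cells) + f"   {mark}")
    return "\n".join(lines)
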