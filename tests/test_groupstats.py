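"""Category summaries, ANOVA/post-hoc/Kruskal-Wallis, link density,
distance stratification, decorrelation index and CRS-R correlations."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from docfc.connectivity import ConnectivityResult
from docfc.groupstats import (
    crsr_correlation, decorrelation_index, distance_stratified_compare,
    homologue_pair_values, kruskal_wallis_by_category, link_density,
    posthoc_bonferroni, threshold_and_summarize, two_way_anova,
)


def make_result(atlas, values, pvalues, measure="PC", subject="s1", condition="control"):
    return ConnectivityResult(measure, np.asarray(values, dtype=float),
                              np.asarray(pvalues, dtype=float),
                              atlas.names, subject_id=subject, condition=condition)


def symmetric_fixture(atlas4, rng):
    n = 4
    v = rng.normal(size=(n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, np.nan)
    p = rng.uniform(size=(n, n))
    p = (p + p.T) / 2
    np.fill_diagonal(p, np.nan)
    return v, p


class TestThresholdAndSummarize:
    def test_alpha_one_is_a_noop(self, atlas4, rng):
        v, p = symmetric_fixture(atlas4, rng)
        res = make_result(atlas4, v, p)
        summ = threshold_and_summarize(res, atlas4, alpha=1.0)
        masks = atlas4.category_masks(directed=False)
        for cat, mask in masks.items():
            row = summ[summ.category == cat].iloc[0]
            assert row.mean_value == pytest.approx(np.nanmean(v[mask]))
            assert row.rejected_fraction == 0.0

    def test_full_rejection_gives_missing_means(self, atlas4):
        v = np.ones((4, 4))
        p = np.full((4, 4), 0.5)
        summ = threshold_and_summarize(make_result(atlas4, v, p), atlas4, alpha=0.1)
        assert summ.rejected_fraction.eq(1.0).all()
        assert summ.mean_value.isna().all()

    def test_hand_worked_category_means(self, atlas4):
        # atlas4: pairs (0,1) and (2,3) homologue; 0,2 L; 1,3 R
        v = np.full((4, 4), np.nan)
        p = np.full((4, 4), 1.0)
        # HIH pair (0,1) value 0.8 significant; LL pair (0,2): 0.4 significant;
        # RR pair (1,3): 0.6 not significant; LR pairs: (0,3)=0.2 sig, (1,2)=0.1 sig
        coords = {(0, 1): (0.8, 0.01), (0, 2): (0.4, 0.05), (1, 3): (0.6, 0.5),
                  (0, 3): (0.2, 0.02), (1, 2): (0.1, 0.03), (2, 3): (0.7, 0.04)}
        for (i, j), (val, pv) in coords.items():
            v[i, j] = v[j, i] = val
            p[i, j] = p[j, i] = pv
        summ = threshold_and_summarize(make_result(atlas4, v, p), atlas4,
                                       alpha=0.1).set_index("category")
        assert summ.loc["HIH", "mean_value"] == pytest.approx((0.8 + 0.7) / 2)
        assert summ.loc["LL", "mean_value"] == pytest.approx(0.4)
        assert np.isnan(summ.loc["RR", "mean_value"])
        assert summ.loc["RR", "rejected_fraction"] == 1.0
        assert summ.loc["LR", "mean_value"] == pytest.approx(0.15)
        assert summ.loc["TOTAL", "mean_value"] == pytest.approx(
            (0.8 + 0.4 + 0.2 + 0.1 + 0.7) / 5)

    def test_alpha_monotonicity_of_rejected_fraction(self, atlas4, rng):
        v, p = symmetric_fixture(atlas4, rng)
        res = make_result(atlas4, v, p)
        fracs = [threshold_and_summarize(res, atlas4, alpha=a)
                 .set_index("category").loc["TOTAL", "rejected_fraction"]
                 for a in (0.05, 0.1, 0.5, 1.0)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_alpha_out_of_range(self, atlas4, rng):
        v, p = symmetric_fixture(atlas4, rng)
        with pytest.raises(ValueError):
            threshold_and_summarize(make_result(atlas4, v, p), atlas4, alpha=0.0)


def balanced_summaries():
    """Balanced 2-group x 2-category design with known cell values."""
    rows = []
    cells = {("control", "HIH"): [0.8, 0.9, 0.7, 0.8],
             ("control", "LL"): [0.4, 0.5, 0.3, 0.4],
             ("doc", "HIH"): [0.5, 0.6, 0.4, 0.5],
             ("doc", "LL"): [0.4, 0.3, 0.5, 0.4]}
    for (cond, cat), vals in cells.items():
        for k, val in enumerate(vals):
            rows.append({"subject_id": f"{cond}_{k}", "condition": cond,
                         "category": cat, "mean_value": val})
    return pd.DataFrame(rows)


def classical_balanced_anova(df):
    """Closed-form balanced two-way ANOVA decomposition (oracle)."""
    groups = sorted(df.condition.unique())
    cats = sorted(df.category.unique())
    n = len(df) // (len(groups) * len(cats))
    grand = df.mean_value.mean()
    ss_a = sum(n * len(cats) * (df[df.condition == g].mean_value.mean() - grand) ** 2
               for g in groups)
    ss_b = sum(n * len(groups) * (df[df.category == c].mean_value.mean() - grand) ** 2
               for c in cats)
    ss_ab = 0.0
    for g, c in itertools.product(groups, cats):
        cell = df[(df.condition == g) & (df.category == c)].mean_value.mean()
        eff = (cell - df[df.condition == g].mean_value.mean()
               - df[df.category == c].mean_value.mean() + grand)
        ss_ab += n * eff ** 2
    ss_err = 0.0
    for g, c in itertools.product(groups, cats):
        cell = df[(df.condition == g) & (df.category == c)].mean_value
        ss_err += ((cell - cell.mean()) ** 2).sum()
    return ss_a, ss_b, ss_ab, ss_err


class TestTwoWayAnova:
    def test_matches_closed_form_on_balanced_design(self):
        df = balanced_summaries()
        table = two_way_anova(df, ("control", "doc")).set_index("effect")
        ss_a, ss_b, ss_ab, ss_err = classical_balanced_anova(df)
        assert table.loc["group", "sum_sq"] == pytest.approx(ss_a, abs=1e-8)
        assert table.loc["category", "sum_sq"] == pytest.approx(ss_b, abs=1e-8)
        assert table.loc["group:category", "sum_sq"] == pytest.approx(ss_ab, abs=1e-8)
        assert table.loc["residual", "sum_sq"] == pytest.approx(ss_err, abs=1e-8)
        # F = (SS/df) / (SS_err/df_err), df_err = 16 - 4
        f_int = (ss_ab / 1) / (ss_err / 12)
        assert table.loc["group:category", "F"] == pytest.approx(f_int, abs=1e-8)

    def test_null_configuration_not_significant(self, rng):
        rows = []
        for cond in ("control", "doc"):
            for k in range(10):
                for cat in ("HIH", "LL"):
                    rows.append({"subject_id": f"{cond}{k}", "condition": cond,
                                 "category": cat, "mean_value": rng.normal()})
        table = two_way_anova(pd.DataFrame(rows), ("control", "doc"))
        assert (table.dropna(subset=["p"]).p > 1e-4).all()

    def test_underpopulated_group_rejected(self):
        df = balanced_summaries()
        df = df[(df.condition == "control") | (df.subject_id == "doc_0")]
        with pytest.raises(ValueError, match="fewer than 2 subjects"):
            two_way_anova(df, ("control", "doc"))


class TestPosthoc:
    def test_identical_groups_capped_at_one(self):
        df = balanced_summaries()
        df.loc[df.condition == "doc", "mean_value"] = \
            df.loc[df.condition == "control", "mean_value"].to_numpy()
        out = posthoc_bonferroni(df, ("control", "doc"))
        assert (out.p_bonferroni == 1.0).all()

    def test_bonferroni_multiplier(self):
        df = balanced_summaries()
        out = posthoc_bonferroni(df, ("control", "doc"),
                                 categories=["HIH", "LL", "RR", "LR", "TOTAL2"])
        hih = out[out.category == "HIH"].iloc[0]
        assert hih.p_bonferroni == pytest.approx(min(1.0, 5 * hih.p_raw))

    def test_t_statistic_matches_hand_formula(self):
        df = balanced_summaries()
        out = posthoc_bonferroni(df, ("control", "doc")).set_index("category")
        a = df[(df.condition == "control") & (df.category == "HIH")].mean_value
        b = df[(df.condition == "doc") & (df.category == "HIH")].mean_value
        sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (len(a) + len(b) - 2)
        t_hand = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        assert out.loc["HIH", "t"] == pytest.approx(t_hand, abs=1e-10)


class TestKruskalWallis:
    def test_hand_ranked_h(self):
        rows = []
        for cond, vals in (("control", [1, 2, 3]), ("doc", [4, 5, 6])):
            for k, v in enumerate(vals):
                rows.append({"subject_id": f"{cond}{k}", "condition": cond,
                             "category": "HIH", "mean_value": v})
        out = kruskal_wallis_by_category(pd.DataFrame(rows), ("control", "doc"))
        # ranks 1..6, group means 2 and 5: H = 12/(6*7) * 3*((2-3.5)^2+(5-3.5)^2)
        assert out.H.iloc[0] == pytest.approx(12 / 42 * 3 * (1.5 ** 2 + 1.5 ** 2), abs=1e-10)

    def test_monotone_transform_invariance(self, rng):
        rows = []
        vals = rng.normal(size=12)
        for k, v in enumerate(vals):
            rows.append({"subject_id": f"s{k}", "condition": "control" if k < 6 else "doc",
                         "category": "LL", "mean_value": v})
        df = pd.DataFrame(rows)
        h1 = kruskal_wallis_by_category(df, ("control", "doc")).H.iloc[0]
        df2 = df.assign(mean_value=np.exp(df.mean_value))
        h2 = kruskal_wallis_by_category(df2, ("control", "doc")).H.iloc[0]
        assert h1 == pytest.approx(h2, abs=1e-10)

    def test_all_tied_rejected(self):
        df = balanced_summaries().assign(mean_value=1.0)
        with pytest.raises(ValueError, match="tied"):
            kruskal_wallis_by_category(df, ("control", "doc"))


class TestLinkDensity:
    def test_all_significant_ll_count_on_90_atlas(self, atlas90):
        n = 90
        res = ConnectivityResult("TE", np.ones((n, n)), np.full((n, n), 0.01),
                                 atlas90.names)
        assert link_density(res, atlas90, "LL", alpha=0.1) == 45 * 44

    def test_none_significant(self, atlas90):
        n = 90
        res = ConnectivityResult("TE", np.ones((n, n)), np.full((n, n), 0.9),
                                 atlas90.names)
        assert link_density(res, atlas90, "LL", alpha=0.1) == 0

    def test_monotone_in_alpha_and_threshold(self, atlas4, rng):
        v = np.abs(rng.normal(size=(4, 4)))
        p = rng.uniform(size=(4, 4))
        res = ConnectivityResult("TE", v, p, atlas4.names)
        d = [link_density(res, atlas4, "TOTAL", alpha=a) for a in (0.05, 0.2, 1.0)]
        assert d[0] <= d[1] <= d[2]
        t = [link_density(res, atlas4, "TOTAL", alpha=1.0, magnitude_threshold=m)
             for m in (0.0, 0.5, 2.0)]
        assert t[0] >= t[1] >= t[2]


class TestDistanceStratified:
    def test_bin_assignment_hand_check(self, atlas4):
        v = np.full((4, 4), 0.5)
        p = np.full((4, 4), 0.01)
        res = make_result(atlas4, v, p)
        pairs = homologue_pair_values(res, atlas4)
        # centroids: pair (0,1) 20 mm apart, pair (2,3) 60 mm apart (plus jitter-free)
        d01 = np.linalg.norm(atlas4.centroids[0] - atlas4.centroids[1])
        d23 = np.linalg.norm(atlas4.centroids[2] - atlas4.centroids[3])
        assert sorted(pairs.distance_mm.round(3)) == sorted([round(d01, 3), round(d23, 3)])

    def test_single_bin_reduces_to_t_test(self, rng):
        from scipy.stats import ttest_ind
        rows = []
        for cond in ("control", "doc"):
            for k in range(6):
                rows.append({"subject_id": f"{cond}{k}", "condition": cond,
                             "value": rng.normal() + (0.5 if cond == "control" else 0.0),
                             "distance_mm": 10.0})
        df = pd.DataFrame(rows)
        out = distance_stratified_compare(df, ("control", "doc"))
        row = out[out.bin == "<20mm"].iloc[0]
        t, p = ttest_ind(df[df.condition == "control"].value,
                         df[df.condition == "doc"].value)
        assert row.t == pytest.approx(t)
        assert row.p == pytest.approx(p)
        assert out[out.bin != "<20mm"].t.isna().all()


class TestDecorrelationIndex:
    def test_basic_values(self):
        out = decorrelation_index(np.array([0.8, 1.0, 0.5]),
                                  np.array([0.6, 1.0, 0.0]))
        assert out.decorrelation_index.tolist() == pytest.approx([0.25, 0.0, 1.0])

    def test_zero_control_flagged_and_excluded(self):
        out = decorrelation_index(np.array([0.0, 1.0]), np.array([0.5, 0.5]))
        assert out.flagged_zero_control.tolist() == [True, False]
        assert np.isnan(out.decorrelation_index.iloc[0])
        assert not out.rank_top.iloc[0]

    def test_top_and_bottom_ranking(self, rng):
        c = np.linspace(1.0, 2.0, 12)
        p = c - np.linspace(0.0, 1.0, 12)   # increasing index
        out = decorrelation_index(c, p, top_k=5)
        assert out.rank_top.to_numpy()[-5:].all()
        assert out.rank_bottom.to_numpy()[:5].all()


class TestCrsrCorrelation:
    def _manifest(self, rng, n=10):
        rows = []
        for k in range(n):
            rows.append({"subject_id": f"doc_{k}", "condition": "doc",
                         "auditory": int(rng.integers(0, 5)), "visual": int(rng.integers(0, 6)),
                         "motor": int(rng.integers(0, 7)), "oromotor_verbal": int(rng.integers(0, 4)),
                         "communication": int(rng.integers(0, 3)), "arousal": int(rng.integers(0, 4)),
                         "months_since_injury": float(rng.integers(2, 7))})
        df = pd.DataFrame(rows)
        df["crsr_total"] = df[["auditory", "visual", "motor", "oromotor_verbal",
                               "communication", "arousal"]].sum(axis=1)
        return df

    def test_identical_measure_gives_r_one(self, rng):
        manifest = self._manifest(rng)
        measures = pd.DataFrame({"subject_id": manifest.subject_id,
                                 "ll_te": manifest.crsr_total.astype(float)})
        out = crsr_correlation(measures, manifest)
        row = out[(out.measure == "ll_te") & (out.score == "crsr_total")].iloc[0]
        assert row.r == pytest.approx(1.0)

    def test_orthogonalized_measure_near_zero(self, rng):
        manifest = self._manifest(rng, n=40)
        y = rng.normal(size=40)
        x = manifest.crsr_total.to_numpy(dtype=float)
        y = y - np.polyval(np.polyfit(x, y, 1), x)   # residualize against score
        out = crsr_correlation(pd.DataFrame({"subject_id": manifest.subject_id,
                                             "m": y}), manifest)
        row = out[(out.measure == "m") & (out.score == "crsr_total")].iloc[0]
        assert abs(row.r) < 1e-10

    def test_constant_score_reported_missing(self, rng):
        manifest = self._manifest(rng)
        manifest["arousal"] = 2
        measures = pd.DataFrame({"subject_id": manifest.subject_id,
                                 "m": rng.normal(size=len(manifest))})
        out = crsr_correlation(measures, manifest)
        assert np.isnan(out[(out.score == "arousal")].r.iloc[0])

    def test_too_few_scans_rejected(self, rng):
        manifest = self._manifest(rng, n=2)
        measures = pd.DataFrame({"subject_id": manifest.subject_id, "m": [1.0, 2.0]})
        with pytest.raises(ValueError, match="at least 3"):
            crsr_correlation(measures, manifest)
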