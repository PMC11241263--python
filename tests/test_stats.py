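"""Statistical battery checked against independent hand-computed oracles:
the explicit Kruskal–Wallis rank formula, the closed-form 2x2 chi-squared,
and the step-up Benjamini–Hochberg definition."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from clotperv import (
    bh_adjust,
    chi_squared_contingency,
    cohort_summary,
    ks_normality,
    kruskal_wallis,
    pairwise_category_comparisons,
    pearson_by_category,
    strength_label,
)


# ---------------------------------------------------------------------------
# oracles


def kw_rank_formula(groups):
    """H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2, tie-corrected."""
    pooled = np.concatenate(groups)
    ranks = rankdata(pooled)
    n_total = pooled.size
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        start += len(g)
        h += len(g) * (r.mean() - (n_total + 1) / 2) ** 2
    h *= 12.0 / (n_total * (n_total + 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n_total**3 - n_total)
    return h / tie


def bh_step_up(ps):
    """Adjusted p-values straight from the step-up definition."""
    m = len(ps)
    order = np.argsort(ps)
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, ps[idx] * m / rank_from_top)
        adjusted[idx] = running_min
    return adjusted


def chi2_2x2_closed_form(a, b, c, d):
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


# ---------------------------------------------------------------------------


class TestKruskalWallis:
    def test_worked_example_h_72(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.statistic == pytest.approx(7.2)
        assert res.df == 2

    def test_identical_groups_with_ties(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_group_order_invariance(self, rng):
        groups = [rng.normal(size=8), rng.normal(1, 1, size=5), rng.normal(2, 1, size=7)]
        a = kruskal_wallis(groups)
        b = kruskal_wallis(groups[::-1])
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_matches_rank_formula_on_small_instances(self, rng):
        # exhaustive-ish sweep over small integer samples with ties
        for _ in range(50):
            k = rng.integers(2, 4)
            groups = [rng.integers(0, 6, size=rng.integers(2, 6)).astype(float) for _ in range(k)]
            if np.ptp(np.concatenate(groups)) == 0:
                continue
            res = kruskal_wallis(groups)
            assert res.statistic == pytest.approx(kw_rank_formula(groups), rel=1e-12)

    @pytest.mark.parametrize("groups", [[[1.0, 2.0]], [[1.0], []], [[1.0], [2.0]]])
    def test_preconditions(self, groups):
        with pytest.raises(ValueError):
            kruskal_wallis(groups)


class TestChiSquared:
    def test_independent_table(self):
        res = chi_squared_contingency([[10, 10], [10, 10]])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_matches_closed_form_2x2(self):
        a, b, c, d = 20, 5, 5, 20
        res = chi_squared_contingency([[a, b], [c, d]])
        assert res.statistic == pytest.approx(chi2_2x2_closed_form(a, b, c, d))

    def test_row_column_permutation_invariance(self):
        t = np.array([[12, 3, 7], [4, 9, 2]])
        base = chi_squared_contingency(t).statistic
        assert chi_squared_contingency(t[::-1]).statistic == pytest.approx(base)
        assert chi_squared_contingency(t[:, ::-1]).statistic == pytest.approx(base)

    def test_zero_column_dropped_with_note(self):
        res = chi_squared_contingency([[5, 0, 10], [8, 0, 3]])
        assert "column" in res.notes
        assert res.df == 1

    def test_low_expected_count_flagged(self):
        res = chi_squared_contingency([[2, 9], [8, 1]])
        assert "expected count < 5" in res.notes

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            chi_squared_contingency([[0, 0], [0, 0]])

    def test_yates_reduces_statistic(self):
        plain = chi_squared_contingency([[20, 5], [5, 20]]).statistic
        corrected = chi_squared_contingency([[20, 5], [5, 20]], yates=True).statistic
        assert corrected < plain


class TestBHAdjust:
    def test_worked_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_identity(self):
        assert bh_adjust([0.037]) == pytest.approx([0.037])

    def test_all_permutations_match_step_up_definition(self):
        base = [0.005, 0.04, 0.2, 0.8]
        for perm in itertools.permutations(base):
            assert bh_adjust(list(perm)) == pytest.approx(bh_step_up(list(perm)))

    def test_permutation_equivariance(self, rng):
        ps = rng.uniform(size=8)
        perm = rng.permutation(8)
        direct = np.asarray(bh_adjust(ps))
        permuted = np.asarray(bh_adjust(ps[perm]))
        assert permuted == pytest.approx(direct[perm])

    def test_adjusted_at_least_raw_and_capped(self, rng):
        ps = rng.uniform(size=20)
        adj = np.asarray(bh_adjust(ps))
        assert np.all(adj >= ps - 1e-15)
        assert np.all(adj <= 1.0)

    def test_idempotence_never_loses_rejections(self, rng):
        ps = rng.uniform(size=15) ** 2
        once = np.asarray(bh_adjust(ps))
        twice = np.asarray(bh_adjust(once))
        assert (twice < 0.05).sum() >= (once < 0.05).sum()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestKSNormality:
    def test_preconditions(self):
        with pytest.raises(ValueError):
            ks_normality([1.0, 2.0])
        with pytest.raises(ValueError):
            ks_normality([3.0, 3.0, 3.0, 3.0])

    def test_normal_calibration(self, rng):
        # rejection rate at alpha=0.05 close to nominal for normal data
        rejections = sum(
            ks_normality(rng.normal(size=100)).p_value < 0.05 for _ in range(400)
        )
        assert 0.02 <= rejections / 400 <= 0.09

    def test_heavy_tails_detected(self, rng):
        rejections = sum(
            ks_normality(rng.standard_cauchy(size=200)).p_value < 0.05 for _ in range(50)
        )
        assert rejections / 50 > 0.8

    def test_notes_mention_correction(self, rng):
        res = ks_normality(rng.normal(size=30))
        assert "Lilliefors" in res.notes


class TestPearson:
    @pytest.mark.parametrize(
        "r, label",
        [
            (0.45, "moderate"),
            (0.41, "moderate"),
            (0.95, "very strong"),
            (-0.75, "strong"),
            (0.25, "weak"),
            (0.05, "negligible"),
        ],
    )
    def test_strength_bands(self, r, label):
        assert strength_label(r) == label

    def test_perfect_linear_pair(self, rng):
        x = rng.normal(size=20)
        df = pd.DataFrame(
            {
                "dynamic_label": "no_uptake",
                "fibrin_platelet_pct": x,
                "rbc_pct": 2 * x + 1,
                "wbc_pct": rng.normal(size=20),
            }
        )
        res = pearson_by_category(df)
        fibrin_rbc = next(r for r in res if r.pair == ("fibrin_platelet_pct", "rbc_pct"))
        assert fibrin_rbc.r == pytest.approx(1.0)
        assert fibrin_rbc.strength_label == "very strong"

    def test_two_part_composition_perfectly_anticorrelated(self, rng):
        fibrin = rng.uniform(20, 80, size=30)
        df = pd.DataFrame(
            {
                "dynamic_label": "late_uptake",
                "fibrin_platelet_pct": fibrin,
                "rbc_pct": 100 - fibrin,
                "wbc_pct": np.zeros(30),
            }
        )
        res = pearson_by_category(df, pairs=(("fibrin_platelet_pct", "rbc_pct"),))
        assert res[0].r == pytest.approx(-1.0)

    def test_affine_rescaling_invariance(self, rng):
        x = rng.normal(size=25)
        y = 0.5 * x + rng.normal(scale=0.5, size=25)
        base = pd.DataFrame(
            {"dynamic_label": "a", "fibrin_platelet_pct": x, "rbc_pct": y, "wbc_pct": 0.0}
        )
        scaled = base.assign(fibrin_platelet_pct=3.0 * x + 7.0)
        pair = (("fibrin_platelet_pct", "rbc_pct"),)
        r1 = pearson_by_category(base, pairs=pair)[0].r
        r2 = pearson_by_category(scaled, pairs=pair)[0].r
        assert r1 == pytest.approx(r2)

    def test_small_group_and_zero_variance_rejected(self, rng):
        df = pd.DataFrame(
            {"dynamic_label": ["a", "a"], "fibrin_platelet_pct": [1, 2], "rbc_pct": [3, 4], "wbc_pct": [0, 0]}
        )
        with pytest.raises(ValueError, match="n=2"):
            pearson_by_category(df)
        df2 = pd.DataFrame(
            {"dynamic_label": "a", "fibrin_platelet_pct": [1, 1, 1], "rbc_pct": [3, 4, 5], "wbc_pct": 0.0}
        )
        with pytest.raises(ValueError, match="variance"):
            pearson_by_category(df2, pairs=(("fibrin_platelet_pct", "rbc_pct"),))


class TestPairwiseComparisons:
    def test_extreme_association_detected(self):
        rows = []
        for cat, rich_n, other_n in [("uptake_with_washout", 30, 5), ("uptake_without_washout", 2, 33)]:
            rows += [{"dynamic_label": cat, "clot_type": "fibrin_platelet_rich"}] * rich_n
            rows += [{"dynamic_label": cat, "clot_type": "mixed"}] * other_n
        res = pairwise_category_comparisons(pd.DataFrame(rows))
        assert len(res) == 1
        assert res[0].p_adjusted < 0.001

    def test_identical_proportions_statistic_zero(self):
        rows = []
        for cat in ("no_uptake", "late_uptake"):
            rows += [{"dynamic_label": cat, "clot_type": "fibrin_platelet_rich"}] * 10
            rows += [{"dynamic_label": cat, "clot_type": "rbc_rich"}] * 10
        res = pairwise_category_comparisons(pd.DataFrame(rows))
        assert res[0].statistic == pytest.approx(0.0)

    def test_degenerate_pair_scores_no_evidence(self):
        rows = [{"dynamic_label": c, "clot_type": "mixed"} for c in ["a"] * 5 + ["b"] * 5]
        res = pairwise_category_comparisons(pd.DataFrame(rows))
        assert res[0].p_value == 1.0
        assert "degenerate" in res[0].notes

    def test_single_category_rejected(self):
        df = pd.DataFrame({"dynamic_label": ["a"] * 4, "clot_type": ["mixed"] * 4})
        with pytest.raises(ValueError):
            pairwise_category_comparisons(df)

    def test_family_adjusted_together(self):
        rows = []
        for cat, rich in [("a", 9), ("b", 5), ("c", 1)]:
            rows += [{"dynamic_label": cat, "clot_type": "fibrin_platelet_rich"}] * rich
            rows += [{"dynamic_label": cat, "clot_type": "mixed"}] * (10 - rich)
        res = pairwise_category_comparisons(pd.DataFrame(rows))
        assert len(res) == 3
        raw = [r.p_value for r in res]
        assert [r.p_adjusted for r in res] == pytest.approx(bh_step_up(raw))


class TestCohortSummary:
    def test_printed_percentages(self):
        df = pd.DataFrame(
            {
                "site_of_occlusion": ["MCA"] * 28 + ["other"] * 11,
                "sex": ["female"] * 19 + ["male"] * 20,
            }
        )
        table = cohort_summary(df, categorical=("site_of_occlusion", "sex"), numeric=())
        cat = table.categorical.set_index(["variable", "level"])
        assert cat.loc[("site_of_occlusion", "MCA"), "percentage"] == 71.8
        assert round(cat.loc[("sex", "female"), "percentage"]) == 49

    def test_counts_sum_to_n(self, small_cohort_config):
        from clotperv import cohort_to_frame, generate_cohort

        df = cohort_to_frame(generate_cohort(small_cohort_config))
        table = cohort_summary(df)
        for _, grp in table.categorical.groupby("variable"):
            assert grp["count"].sum() == table.n

    def test_single_patient_every_level_100(self):
        df = pd.DataFrame({"sex": ["female"], "mtici": ["3"], "age": [70]})
        table = cohort_summary(df, categorical=("sex", "mtici"), numeric=("age",))
        assert (table.categorical["percentage"] == 100.0).all()

    def test_numeric_mean_sd(self):
        df = pd.DataFrame({"age": [60.0, 70.0, 80.0]})
        table = cohort_summary(df, categorical=(), numeric=("age",))
        row = table.numeric.iloc[0]
        assert row["mean"] == pytest.approx(70.0)
        assert row["sd"] == pytest.approx(10.0)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_summary(pd.DataFrame())
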