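"""Cohort statistics: Mann-Whitney AUC, Wilcoxon tests, threshold
simulation, ROC-optimal cuts, and unified flagging."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from megabn.cohort import (
    CohortTable,
    ThresholdSet,
    analytic_max_abs_z_threshold,
    auc_mwu,
    flag_failures,
    optimal_threshold,
    simulate_max_abs_z_threshold,
    unified_outcome_analysis,
    wilcoxon_one_sample,
)
from megabn.cohort import _signed_rank_exact_p
from megabn.markers import MarkerSet, drs
from conftest import make_abnormality
from test_markers import make_mask


def auc_oracle(x, y):
    """Fraction of (x, y) pairs with x > y, ties one half."""
    total = sum(1.0 if a > b else (0.5 if a == b else 0.0) for a in x for b in y)
    return total / (len(x) * len(y))


class TestAucMwu:
    def test_complete_separation(self):
        auc, p = auc_mwu([5, 6], [1, 2], alternative="greater")
        assert auc == 1.0
        assert p == pytest.approx(1 / 6)  # exact: 1 / C(4, 2)

    def test_partial_overlap(self):
        auc, p = auc_mwu([3, 1], [2, 0], alternative="greater")
        assert auc == 0.75
        assert p == pytest.approx(1 / 3)  # P(U >= 3) over the 6 splits

    def test_orientation_flips_with_alternative(self):
        auc_g, _ = auc_mwu([5, 6], [1, 2], alternative="greater")
        auc_l, _ = auc_mwu([5, 6], [1, 2], alternative="less")
        assert auc_g == 1.0 and auc_l == 0.0

    def test_group_swap_complement(self, rng):
        x = rng.integers(0, 5, 12).astype(float)
        y = rng.integers(0, 5, 9).astype(float)
        a1, _ = auc_mwu(x, y, alternative="greater")
        a2, _ = auc_mwu(y, x, alternative="greater")
        assert a1 == pytest.approx(1.0 - a2)

    @given(
        x=st.lists(st.integers(0, 6), min_size=1, max_size=12),
        y=st.lists(st.integers(0, 6), min_size=1, max_size=12),
    )
    def test_auc_matches_pair_count_oracle(self, x, y):
        auc, _ = auc_mwu(x, y, alternative="greater")
        assert auc == pytest.approx(auc_oracle(x, y), abs=1e-12)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="non-empty"):
            auc_mwu([], [1.0])

    def test_shares_the_drs_kernel(self, rng):
        """AUC with spared as the hypothesised-greater group equals D_RS."""
        res = rng.uniform(0, 5, 10)
        spa = rng.uniform(0, 5, 20)
        scores = {f"R{i}": v for i, v in enumerate(res)}
        scores.update({f"S{i}": v for i, v in enumerate(spa)})
        abn = make_abnormality(scores)
        mask = make_mask([f"R{i}" for i in range(10)], [f"S{i}" for i in range(20)])
        auc, _ = auc_mwu(spa, res, alternative="greater")
        assert auc == pytest.approx(drs(abn, mask), abs=1e-12)

    def test_null_type_one_error_at_most_nominal(self):
        rng = np.random.default_rng(42)
        rejections = 0
        for _ in range(1000):
            g = rng.standard_normal(8)
            b = rng.standard_normal(8)
            _, p = auc_mwu(g, b, alternative="greater")
            rejections += p < 0.05
        # exact test is conservative; allow binomial noise above 5%
        assert rejections / 1000 <= 0.07


class TestWilcoxonOneSample:
    def test_all_positive_small_sample_exact_p(self):
        w, p = wilcoxon_one_sample([3, 4, 5], 2.6, alternative="greater")
        assert w == 6.0
        assert p == pytest.approx(1 / 8)  # one of 2^3 sign patterns

    def test_smallest_attainable_p_with_tied_ranks(self):
        w, p = wilcoxon_one_sample([0.1, 0.2, 0.1, 0.3, 0.1], 0.5, alternative="less")
        assert w == 0.0
        assert p == pytest.approx(1 / 32)

    def test_all_zero_differences_raise(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_one_sample([2.6, 2.6], 2.6)

    def test_matches_scipy_exact_without_ties(self, rng):
        for _ in range(20):
            d = rng.standard_normal(12)
            for alt in ("greater", "less"):
                _, p = wilcoxon_one_sample(d, 0.0, alternative=alt)
                ref = stats.wilcoxon(d, alternative=alt, method="exact").pvalue
                assert p == pytest.approx(ref, rel=1e-10)

    def test_normal_approximation_close_to_exact_enumeration(self, rng):
        """Above the exact-regime cutoff the tie-corrected normal
        approximation should track the exact null distribution."""
        d = rng.integers(-6, 7, 30)
        d = d[d != 0].astype(float)
        assert d.size > 25
        w, p_approx = wilcoxon_one_sample(d, 0.0, alternative="greater")
        ranks = stats.rankdata(np.abs(d))
        p_exact = _signed_rank_exact_p(
            np.rint(2 * ranks).astype(int), 2 * ranks[d > 0].sum(), "greater"
        )
        assert p_approx == pytest.approx(p_exact, abs=0.01)

    def test_symmetric_null_gives_p_about_half_on_average(self):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(400):
            vals = 0.5 + rng.standard_normal(15)
            ps.append(wilcoxon_one_sample(vals, 0.5, alternative="less")[1])
        assert np.mean(ps) == pytest.approx(0.5, abs=0.04)


class TestThresholdSimulation:
    def test_reproduces_the_healthy_five_band_threshold(self):
        t = simulate_max_abs_z_threshold(n_bands=5, n_iter=100_000, alpha=0.05, seed=0)
        assert t == pytest.approx(analytic_max_abs_z_threshold(5, 0.05), abs=0.02)

    def test_single_band_recovers_the_two_sided_normal_quantile(self):
        t = simulate_max_abs_z_threshold(n_bands=1, n_iter=100_000, alpha=0.05, seed=0)
        assert t == pytest.approx(1.959964, abs=0.03)

    def test_reproducible_given_seed(self):
        t1 = simulate_max_abs_z_threshold(seed=5)
        t2 = simulate_max_abs_z_threshold(seed=5)
        assert t1 == t2

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.1])
    def test_invalid_alpha_rejected(self, alpha):
        with pytest.raises(ValueError, match="alpha"):
            simulate_max_abs_z_threshold(alpha=alpha)

    def test_closed_form_inverts_the_max_order_statistic_cdf(self):
        t = analytic_max_abs_z_threshold(5, 0.05)
        assert (2 * stats.norm.cdf(t) - 1) ** 5 == pytest.approx(0.95, abs=1e-12)


def youden_oracle(values, is_bad, direction):
    values = np.asarray(values, dtype=float)
    uniq = np.unique(values)
    cuts = np.concatenate([[-np.inf], (uniq[:-1] + uniq[1:]) / 2, [np.inf]])
    best_j = -np.inf
    for t in cuts:
        flagged = values < t if direction == "low" else values > t
        j = flagged[is_bad].mean() - flagged[~is_bad].mean()
        best_j = max(best_j, j)
    return best_j, cuts


class TestOptimalThreshold:
    def test_complete_separation_returns_gap_midpoint(self):
        t = optimal_threshold([1, 2, 5, 6], [1, 1, 0, 0], failure_direction="low")
        assert t == 3.5

    def test_degenerate_equal_values_flag_nobody(self):
        t = optimal_threshold([2.0, 2.0, 2.0], [1, 0, 1], failure_direction="low")
        assert t == -np.inf

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="classes"):
            optimal_threshold([1, 2], [1, 1], failure_direction="low")

    @given(
        data=st.lists(
            st.tuples(st.integers(0, 10), st.booleans()), min_size=4, max_size=12
        ).filter(lambda d: len({b for _, b in d}) == 2),
        direction=st.sampled_from(["low", "high"]),
    )
    def test_achieves_the_exhaustive_scan_optimum(self, data, direction):
        values = [float(v) for v, _ in data]
        is_bad = np.array([b for _, b in data])
        t = optimal_threshold(values, is_bad, failure_direction=direction)
        v = np.asarray(values)
        flagged = v < t if direction == "low" else v > t
        j = flagged[is_bad].mean() - flagged[~is_bad].mean()
        best_j, _ = youden_oracle(values, is_bad, direction)
        assert j == pytest.approx(best_j, abs=1e-12)

    def test_corner_method_agrees_on_separable_data(self):
        t_y = optimal_threshold([1, 2, 5, 6], [1, 1, 0, 0], "low", method="youden")
        t_c = optimal_threshold([1, 2, 5, 6], [1, 1, 0, 0], "low", method="corner")
        assert t_y == t_c == 3.5


def cohort_from(triples, outcomes):
    markers = [MarkerSet(f"p{i}", *t) for i, t in enumerate(triples)]
    return CohortTable(markers=markers, outcomes=outcomes)


class TestFlagFailures:
    def test_strict_inequalities_at_the_published_boundaries(self):
        cohort = cohort_from([(3.35, 0.34, 9.58)], ["good"])
        flags = flag_failures(cohort, ThresholdSet(3.35, 0.34, 9.58))[0]
        assert flags.flags == (False, False, False)  # boundary equality never flags
        flags2 = flag_failures(
            cohort_from([(3.34, 0.35, 9.57)], ["bad"]), ThresholdSet(3.35, 0.34, 9.58)
        )[0]
        assert flags2.flags == (True, True, True)
        assert flags2.n_flags == 3

    def test_raising_mar_threshold_never_clears_a_flag(self, rng):
        cohort = cohort_from(
            [(float(v), 0.5, 50.0) for v in rng.uniform(0, 8, 20)], ["good"] * 20
        )
        flagged_before = set()
        for thresh in [1.0, 2.5, 4.0, 6.0]:
            now = {
                f.subject_id
                for f in flag_failures(cohort, ThresholdSet(thresh, 1.0, 0.0))
                if f.mechanism_1
            }
            assert flagged_before <= now
            flagged_before = now


class TestUnifiedAnalysis:
    def test_constructed_separation_yields_perfect_flagging(self):
        good = [(6.0 + i / 10, 0.05 + i / 100, 30.0 + i) for i in range(5)]
        bad = [(1.0 + i / 10, 0.80 + i / 100, 5.0 + i / 10) for i in range(6)]
        cohort = cohort_from(good + bad, ["good"] * 5 + ["bad"] * 6)
        report = unified_outcome_analysis(cohort)
        assert report.group_flag_rates["bad"]["at_least_1"] == 1.0
        assert report.group_flag_rates["good"]["none"] == 1.0
        assert report.n_flags_auc == 1.0
        for st_ in report.marker_stats.values():
            assert st_["auc"] == 1.0

    def test_outcome_independent_markers_give_chance_auc_on_average(self):
        rng = np.random.default_rng(9)
        aucs = []
        for _ in range(200):
            triples = [
                (float(rng.uniform(0, 6)), float(rng.uniform(0, 1)),
                 float(rng.uniform(0, 100)))
                for _ in range(16)
            ]
            cohort = cohort_from(triples, ["good"] * 8 + ["bad"] * 8)
            report = unified_outcome_analysis(cohort)
            aucs.append([report.marker_stats[m]["auc"] for m in ("MA_R", "D_RS", "AC_R")])
        mean_aucs = np.mean(aucs, axis=0)
        np.testing.assert_allclose(mean_aucs, 0.5, atol=0.05)

    def test_report_serialises_to_plain_types(self):
        cohort = cohort_from(
            [(6.0, 0.1, 30.0), (5.0, 0.2, 25.0), (1.0, 0.8, 5.0), (2.0, 0.7, 6.0)],
            ["good", "good", "bad", "bad"],
        )
        import json

        d = unified_outcome_analysis(cohort).to_dict()
        json.dumps(d)  # must not raise
        assert set(d["thresholds"]) == {"MA_R", "D_RS", "AC_R"}
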