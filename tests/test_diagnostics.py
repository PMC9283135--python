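"""Accuracy indices, chi-square, group comparisons, per-point logistic risk."""

import math

import numpy as np
import pytest
import scipy.stats

from moca_psci import (
    ContingencyTable2x2,
    accuracy_indices,
    build_contingency,
    compare_groups,
    fit_logistic,
    pearson_chi2,
    proportion,
)
from moca_psci.diagnostics import format_p, round_half_up


def table_from_counts(tp, fp, fn, tn):
    perfs = ["impaired"] * (tp + fp) + ["normal"] * (fn + tn)
    outcomes = [True] * tp + [False] * fp + [True] * fn + [False] * tn
    return build_contingency(perfs, outcomes)


class TestContingency:
    def test_counts_partition_n(self):
        t = table_from_counts(36, 2, 41, 39)
        assert (t.tp, t.fp, t.fn, t.tn) == (36, 2, 41, 39)
        assert t.total == 118

    def test_hand_counted_small_vector(self):
        t = build_contingency(["impaired", "normal", "impaired", "normal"],
                              [True, True, False, False])
        assert (t.tp, t.fp, t.fn, t.tn) == (1, 1, 1, 1)

    def test_all_impaired_all_psci(self):
        t = build_contingency(["impaired"] * 5, [True] * 5)
        assert (t.tp, t.fp, t.fn, t.tn) == (5, 0, 0, 0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            build_contingency(["impaired"], [True, False])


class TestAccuracyIndices:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            # (tp, fp, fn, tn) -> Se, Sp, PPV, NPV integer percents
            ((36, 2, 41, 39), (47, 95, 95, 49)),
            ((31, 2, 46, 39), (40, 95, 94, 46)),
            ((27, 1, 50, 40), (35, 98, 96, 44)),
        ],
    )
    def test_screening_table_cells(self, counts, expected):
        """Half-up integer percents of the three normative-threshold tables."""
        acc = accuracy_indices(ContingencyTable2x2(*counts)).as_percents()
        assert (acc["sensitivity"], acc["specificity"], acc["ppv"], acc["npv"]) == expected

    def test_zero_denominator_is_undefined_not_extreme(self):
        acc = accuracy_indices(ContingencyTable2x2(0, 0, 0, 5))
        assert acc.sensitivity is None and acc.ppv is None
        assert acc.specificity == 1.0 and acc.npv == 1.0

    def test_label_swap_exchanges_se_sp_and_ppv_npv(self, rng):
        for _ in range(50):
            tp, fp, fn, tn = rng.integers(1, 40, size=4)
            a = accuracy_indices(ContingencyTable2x2(int(tp), int(fp), int(fn), int(tn)))
            # swapping the outcome labels turns tp<->tn, fp<->fn
            b = accuracy_indices(ContingencyTable2x2(int(tn), int(fn), int(fp), int(tp)))
            assert b.sensitivity == pytest.approx(a.specificity)
            assert b.specificity == pytest.approx(a.sensitivity)
            assert b.ppv == pytest.approx(a.npv)
            assert b.npv == pytest.approx(a.ppv)

    def test_prevalence_identity(self, rng):
        """PPV/NPV via Bayes from (Se, Sp, prevalence) equal the direct ratios."""
        for _ in range(50):
            tp, fp, fn, tn = (int(v) for v in rng.integers(1, 40, size=4))
            acc = accuracy_indices(ContingencyTable2x2(tp, fp, fn, tn))
            prev = (tp + fn) / (tp + fp + fn + tn)
            se, sp = acc.sensitivity, acc.specificity
            ppv = se * prev / (se * prev + (1 - sp) * (1 - prev))
            npv = sp * (1 - prev) / (sp * (1 - prev) + (1 - se) * prev)
            assert acc.ppv == pytest.approx(ppv, abs=1e-12)
            assert acc.npv == pytest.approx(npv, abs=1e-12)


class TestChiSquare:
    def test_identical_rows_give_zero(self):
        stat, p = pearson_chi2(ContingencyTable2x2(10, 10, 10, 10))
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_screening_table_is_highly_significant(self):
        _, p = pearson_chi2(ContingencyTable2x2(36, 2, 41, 39))
        assert p < 0.001

    def test_matches_expected_count_formula(self, rng):
        """Pearson X^2 equals the textbook sum of (O-E)^2/E (no correction)."""
        for _ in range(50):
            tp, fp, fn, tn = (int(v) for v in rng.integers(1, 60, size=4))
            obs = np.array([[tp, fp], [fn, tn]], dtype=float)
            total = obs.sum()
            expected = np.outer(obs.sum(1), obs.sum(0)) / total
            oracle = ((obs - expected) ** 2 / expected).sum()
            stat, p = pearson_chi2(ContingencyTable2x2(tp, fp, fn, tn))
            assert stat == pytest.approx(oracle, abs=1e-10)
            assert p == pytest.approx(scipy.stats.chi2.sf(oracle, 1), abs=1e-12)

    def test_zero_marginal_inestimable(self):
        with pytest.raises(ValueError, match="marginal"):
            pearson_chi2(ContingencyTable2x2(0, 0, 10, 10))


def _grid_search_logistic(x, y, span=10.0, steps=81, rounds=12):
    """Exhaustive refinement search over (intercept, coefficient).

    Runs on the centered covariate (where the two parameters are nearly
    orthogonal) and converts back, so the rectangular grid can actually
    reach the maximum.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xbar = x.mean()
    xc = x - xbar
    best = (0.0, 0.0)  # (intercept on centered scale, slope)
    width = span
    for _ in range(rounds):
        b0s = np.linspace(best[0] - width, best[0] + width, steps)
        b1s = np.linspace(best[1] - width, best[1] + width, steps)
        ll = (y[None, None, :] * (b0s[:, None, None] + b1s[None, :, None] * xc)
              - np.logaddexp(0, b0s[:, None, None] + b1s[None, :, None] * xc)).sum(axis=2)
        i, j = np.unravel_index(int(np.argmax(ll)), ll.shape)
        best = (b0s[i], b1s[j])
        width /= 3.0
    return best[0] - best[1] * xbar, best[1]


class TestLogisticRisk:
    def test_null_effect_gives_or_near_one(self, rng):
        x = rng.normal(20, 5, size=4000)
        y = rng.random(4000) < 0.5
        fit = fit_logistic(x, y)
        assert fit.converged
        assert fit.ci95[0] < 1.0 < fit.ci95[1]
        assert fit.odds_ratio_per_point_lost == pytest.approx(1.0, abs=0.1)

    def test_recovers_generative_or(self, rng):
        """OR 1.39 per point lost, n = 5000: estimate within its own Wald CI."""
        beta = -math.log(1.39)
        x = rng.normal(20, 6, size=5000)
        p = 1 / (1 + np.exp(-(7.0 + beta * x)))  # intercept 7 puts prevalence mid-range
        y = rng.random(5000) < p
        fit = fit_logistic(x, y)
        assert fit.converged
        assert fit.ci95[0] <= 1.39 <= fit.ci95[1]
        assert fit.odds_ratio_per_point_lost == pytest.approx(1.39, rel=0.05)

    def test_matches_grid_search_on_tiny_dataset(self):
        x = [12.0, 14.5, 16.0, 17.5, 19.0, 21.0, 22.5, 24.0, 26.0, 27.5, 29.0, 30.0]
        y = [1, 1, 1, 0, 1, 1, 0, 0, 1, 0, 0, 0]
        fit = fit_logistic(x, y)
        b0, b1 = _grid_search_logistic(x, y)
        assert fit.intercept == pytest.approx(b0, abs=1e-3)
        assert fit.coefficient == pytest.approx(b1, abs=1e-4)
        assert fit.odds_ratio_per_point_lost == pytest.approx(math.exp(-b1), rel=1e-3)

    def test_shift_invariance_of_or(self, rng):
        x = rng.normal(20, 5, size=800)
        y = rng.random(800) < 1 / (1 + np.exp(0.3 * (x - 20)))
        f1 = fit_logistic(x, y)
        f2 = fit_logistic(x + 100.0, y)
        assert f2.odds_ratio_per_point_lost == pytest.approx(
            f1.odds_ratio_per_point_lost, rel=1e-5)
        assert f2.coefficient == pytest.approx(f1.coefficient, abs=1e-6)

    def test_separation_reported_not_raised(self):
        x = list(range(20))
        y = [v >= 10 for v in x]
        fit = fit_logistic(x, y)
        assert not fit.converged
        assert fit.message

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(list(range(12)), [True] * 12)


class TestProportionAndFormatting:
    @pytest.mark.parametrize(
        "count, total, decimals, expected",
        [(77, 118, 0, 65.0), (118, 207, 0, 57.0), (85, 207, 0, 41.0),
         (59, 207, 1, 28.5), (0, 50, 0, 0.0), (1, 8, 0, 13.0)],
    )
    def test_half_up_percent(self, count, total, decimals, expected):
        assert proportion(count, total, decimals) == expected

    def test_half_up_not_bankers(self):
        # 46.75 -> 47 and 0.5 -> 1, where banker's rounding would go down
        assert round_half_up(46.75) == 47
        assert proportion(1, 2, 0) == 50.0
        assert proportion(5, 1000, 0) == 1.0  # 0.5% -> 1%

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            proportion(0, 0)

    def test_p_value_rendering(self):
        assert format_p(0.0004) == "<0.001"
        assert format_p(0.021) == "0.021"


class TestCompareGroups:
    def test_identical_numeric_groups(self):
        cmp = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], kind="t")
        assert cmp.statistic == pytest.approx(0.0)
        assert cmp.p == pytest.approx(1.0)

    def test_textbook_two_sample_t(self):
        """Pooled t on a hand-checked pair of samples."""
        a = [19.0, 22.0, 24.0, 27.0]
        b = [28.0, 31.0, 33.0, 36.0]
        cmp = compare_groups(a, b, kind="t")
        stat, p = scipy.stats.ttest_ind(a, b, equal_var=True)
        assert cmp.statistic == pytest.approx(float(stat), abs=1e-10)
        assert cmp.p == pytest.approx(float(p), abs=1e-10)
        # hand check: pooled var = 68/6, se = sqrt(11.333/2), t = -9/2.3805
        assert cmp.statistic == pytest.approx(-3.781, abs=1e-3)

    def test_detects_generated_age_gap_direction(self, rng):
        followed = rng.normal(74.7, 9, size=1200)
        dropouts = rng.normal(77.7, 10, size=800)
        cmp = compare_groups(followed, dropouts, variable="age", kind="t")
        assert cmp.statistic < 0  # drop-outs older
        assert cmp.p < 0.01

    def test_binary_variable_uses_chi2(self):
        cmp = compare_groups([1.0] * 30 + [0.0] * 70, [1.0] * 50 + [0.0] * 50)
        assert cmp.kind == "chi2"
        assert cmp.p < 0.05

    def test_zero_variance_inestimable(self):
        with pytest.raises(ValueError):
            compare_groups([5.0, 5.0], [5.0, 5.0], kind="t")
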