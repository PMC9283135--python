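"""ROC construction, AUC/concordance equivalence, optimal cut-off selection."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from moca_psci import roc_points, select_optimal, threshold_table


def concordance(values, outcomes):
    """O(n^2) pairwise oracle: P(score_pos < score_neg) + 0.5 P(tie)."""
    pos = [v for v, o in zip(values, outcomes) if o]
    neg = [v for v, o in zip(values, outcomes) if not o]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p < n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_se_sp(values, outcomes, threshold):
    """Direct recount at one threshold under the 'positive iff value < t' rule."""
    values = np.asarray(values)
    outcomes = np.asarray(outcomes, bool)
    positive = values < threshold
    se = (positive & outcomes).sum() / outcomes.sum()
    sp = (~positive & ~outcomes).sum() / (~outcomes).sum()
    return se, sp


class TestRocPoints:
    def test_perfect_separation(self):
        curve = roc_points([1, 2, 3, 4], [True, True, False, False])
        assert curve.auc == pytest.approx(1.0)
        perfect = [p for p in curve.points
                   if p.sensitivity == 1.0 and p.specificity == 1.0]
        assert perfect and perfect[0].threshold == pytest.approx(2.5)

    def test_all_ties_degenerate(self):
        curve = roc_points([5.0] * 8, [True] * 4 + [False] * 4)
        assert curve.auc == pytest.approx(0.5)
        pairs = {(p.sensitivity, p.specificity) for p in curve.points}
        assert pairs == {(1.0, 0.0), (0.0, 1.0)}

    def test_endpoints_present(self, rng):
        curve = roc_points(rng.normal(20, 5, 30), rng.random(30) < 0.5)
        pairs = {(p.sensitivity, p.specificity) for p in curve.points}
        assert (1.0, 0.0) in pairs and (0.0, 1.0) in pairs

    def test_monotone_along_decreasing_thresholds(self, rng):
        values = rng.normal(20, 5, 80)
        curve = roc_points(values, rng.random(80) < 0.4)
        ts = [p.threshold for p in curve.points]
        assert all(a > b for a, b in zip(ts, ts[1:]))
        ses = [p.sensitivity for p in curve.points]
        sps = [p.specificity for p in curve.points]
        assert all(a >= b for a, b in zip(ses, ses[1:]))
        assert all(a <= b for a, b in zip(sps, sps[1:]))

    def test_every_point_matches_brute_force_recount(self, rng):
        values = np.round(rng.normal(20, 5, 50), 1)  # ties on purpose
        outcomes = rng.random(50) < 0.5
        curve = roc_points(values, outcomes)
        for p in curve.points:
            se, sp = brute_force_se_sp(values, outcomes, p.threshold)
            assert p.sensitivity == pytest.approx(se, abs=1e-12)
            assert p.specificity == pytest.approx(sp, abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_points([1, 2, 3, 4], [True] * 4)


class TestAuc:
    def test_equals_concordance_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 50))
            values = np.round(rng.normal(0, 1, n), 1)
            outcomes = rng.random(n) < 0.5
            if outcomes.all() or not outcomes.any():
                continue
            curve = roc_points(values, outcomes)
            assert curve.auc == pytest.approx(concordance(values, outcomes), abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        values = rng.normal(20, 6, 300)
        outcomes = rng.random(300) < 0.5
        curve = roc_points(values, outcomes)
        # sklearn scores 'higher = positive'; our positive is low score
        assert curve.auc == pytest.approx(roc_auc_score(outcomes, -values), abs=1e-12)

    def test_negation_invariance(self, rng):
        values = rng.normal(0, 1, 40)
        outcomes = rng.random(40) < 0.5
        if outcomes.all() or not outcomes.any():
            outcomes[0] = ~outcomes[0]
        a = roc_points(values, outcomes).auc
        b = roc_points(-values, ~outcomes).auc  # flip scores and orientation
        assert a == pytest.approx(b, abs=1e-12)


class TestThresholdTable:
    def test_perfect_toy_single_optimal_row(self):
        curve = roc_points([1, 2, 3, 4], [True, True, False, False])
        table = threshold_table(curve)
        flagged = table[table.optimal]
        assert len(flagged) == 1
        assert flagged.iloc[0].sensitivity_pct == 100
        assert flagged.iloc[0].specificity_pct == 100

    def test_row_count_is_midpoints_plus_sentinels(self, rng):
        values = rng.normal(20, 5, 60)
        curve = roc_points(values, rng.random(60) < 0.5)
        n_distinct = len(np.unique(values))
        assert len(threshold_table(curve)) == n_distinct + 1

    def test_range_restriction(self, rng):
        values = rng.normal(20, 5, 60)
        curve = roc_points(values, rng.random(60) < 0.5)
        sub = threshold_table(curve, around=(18, 22))
        assert ((sub.threshold >= 18) & (sub.threshold <= 22)).all()

    def test_optimal_row_matches_select_optimal(self, rng):
        values = rng.normal(20, 5, 100)
        outcomes = rng.random(100) < 1 / (1 + np.exp(0.4 * (values - 20)))
        curve = roc_points(values, outcomes)
        best = select_optimal(curve)
        flagged = threshold_table(curve)[lambda df: df.optimal].iloc[0]
        assert flagged.threshold == pytest.approx(best.threshold)
        assert flagged.sensitivity_pct == pytest.approx(100 * best.sensitivity, abs=0.5)
        assert flagged.specificity_pct == pytest.approx(100 * best.specificity, abs=0.5)


class TestSelectOptimal:
    def test_adequate_point_selected(self, rng):
        """A well-separated cohort yields an adequate screening cut-off."""
        pos = rng.normal(16, 4, 300)
        neg = rng.normal(24, 3, 200)
        values = np.concatenate([pos, neg])
        outcomes = np.array([True] * 300 + [False] * 200)
        best = select_optimal(roc_points(values, outcomes))
        assert best.adequate
        assert best.sensitivity >= 0.80 and best.specificity >= 0.60
        assert best.youden == pytest.approx(best.sensitivity + best.specificity - 1)

    def test_inadequate_curve_falls_back_to_global_youden(self, rng):
        """Overlapping classes: no point reaches Se>=0.80 & Sp>=0.60."""
        pos = rng.normal(19.5, 5, 200)
        neg = rng.normal(20.5, 5, 200)
        values = np.concatenate([pos, neg])
        outcomes = np.array([True] * 200 + [False] * 200)
        curve = roc_points(values, outcomes)
        assert not any(p.sensitivity >= 0.8 and p.specificity >= 0.6
                       for p in curve.points)
        best = select_optimal(curve)
        assert not best.adequate
        assert best.youden == pytest.approx(max(p.youden for p in curve.points))

    def test_perfect_separation_is_adequate(self):
        best = select_optimal(roc_points([1, 2, 3, 4], [True, True, False, False]))
        assert best.adequate
        assert best.sensitivity == 1.0 and best.specificity == 1.0

    def test_selected_point_is_a_curve_row(self, rng):
        values = rng.normal(20, 6, 150)
        outcomes = rng.random(150) < 1 / (1 + np.exp(0.3 * (values - 19)))
        curve = roc_points(values, outcomes)
        best = select_optimal(curve)
        assert any(p.threshold == best.threshold
                   and p.sensitivity == best.sensitivity
                   and p.specificity == best.specificity
                   for p in curve.points)

    def test_converges_to_analytic_crossing_point(self, rng):
        """Equal-variance normal classes: the Youden-optimal threshold is the
        midpoint of the class means; check convergence at n = 10^4."""
        mu_pos, mu_neg, sd = 16.0, 24.0, 4.0
        n = 10_000
        values = np.concatenate([rng.normal(mu_pos, sd, n // 2),
                                 rng.normal(mu_neg, sd, n // 2)])
        outcomes = np.array([True] * (n // 2) + [False] * (n // 2))
        best = select_optimal(roc_points(values, outcomes))
        assert best.threshold == pytest.approx((mu_pos + mu_neg) / 2, abs=0.35)
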