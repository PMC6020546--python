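"""Tests of the statistical kernels (against independent enumeration and
closed-form oracles) and of the sweep driver's structure."""

import itertools
import math

import numpy as np
import pytest

import egmentropy as eg
from egmentropy.robustness import (
    ROBUSTNESS_THRESHOLD,
    dispersion_interval,
    fit_linear_trend,
    mann_whitney_u,
    pearson_correlation,
    roc_curve,
    run_sweep,
)


def exact_mann_whitney_p(a, b):
    """Independent oracle: full enumeration of rank splits.

    Two-sided p = probability, under random assignment of the pooled
    observations to groups, of a U at least as extreme as observed
    (doubling the smaller tail, capped at 1). Assumes no ties.
    """
    a, b = list(a), list(b)
    pooled = sorted(a + b)
    n1 = len(a)
    u_obs = sum(1 for x in a for y in b if x > y)
    us = [
        sum(1 for x in comb for y in pooled if y not in comb and x > y)
        for comb in itertools.combinations(pooled, n1)
    ]
    total = len(us)
    lo = sum(1 for u in us if u <= u_obs) / total
    hi = sum(1 for u in us if u >= u_obs) / total
    return min(1.0, 2 * min(lo, hi))


class TestMannWhitney:
    def test_matches_enumeration_oracle_on_small_samples(self, rng):
        for _ in range(15):
            n1, n2 = rng.integers(3, 9, size=2)
            a = rng.normal(size=n1)
            b = rng.normal(loc=rng.normal(), size=n2)
            _, p = mann_whitney_u(a, b)
            assert p == pytest.approx(exact_mann_whitney_p(a, b), abs=1e-12)

    def test_disjoint_groups_exact_p(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_groups_no_separation(self):
        _, p = mann_whitney_u(list(range(10)), list(range(10)))
        assert p >= 0.99

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestPearson:
    def test_self_correlation_is_one(self, rng):
        x = rng.normal(size=20)
        assert pearson_correlation(x, x) == pytest.approx(1.0)

    def test_negated_affine_is_minus_one(self, rng):
        x = rng.normal(size=20)
        assert pearson_correlation(x, -x + 3.0) == pytest.approx(-1.0)

    def test_direct_formula_example(self):
        assert pearson_correlation([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestDispersionInterval:
    def test_constant_sample_zero_width(self):
        lo, hi = dispersion_interval([2.0, 2.0, 2.0])
        assert lo == hi == 2.0

    def test_two_point_sample_hand_computed(self):
        lo, hi = dispersion_interval([0.0, 2.0])
        assert lo == pytest.approx(1 - 2 * math.sqrt(2))
        assert hi == pytest.approx(1 + 2 * math.sqrt(2))

    def test_interval_contains_mean(self, rng):
        values = rng.normal(size=30)
        lo, hi = dispersion_interval(values)
        assert lo <= values.mean() <= hi

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            dispersion_interval([1.0])


class TestLinearFit:
    @pytest.mark.parametrize(
        "slope,intercept", [(0.002, 0.19), (0.004, 0.36)]
    )
    def test_exact_line_recovered(self, slope, intercept):
        eta = np.array([0.0, 10.0, 20.0, 30.0, 50.0])
        fit = fit_linear_trend(eta, slope * eta + intercept)
        assert fit.slope == pytest.approx(slope)
        assert fit.intercept == pytest.approx(intercept)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.std_error_pct == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equation_oracle(self, rng):
        x = np.linspace(0, 50, 12)
        y = 0.003 * x + 0.2 + 0.01 * rng.normal(size=12)
        fit = fit_linear_trend(x, y)
        # closed-form normal equations
        X = np.vstack([x, np.ones_like(x)]).T
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.slope == pytest.approx(beta[0], abs=1e-10)
        assert fit.intercept == pytest.approx(beta[1], abs=1e-10)

    def test_degenerate_levels_rejected(self):
        with pytest.raises(ValueError):
            fit_linear_trend([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestROC:
    def test_perfect_separation(self):
        res = roc_curve([0.1, 0.2, 0.8, 0.9], ["NC", "NC", "C", "C"])
        assert res.auc == pytest.approx(1.0)

    def test_negation_antisymmetry(self, rng):
        scores = rng.normal(size=40)
        labels = ["C" if v else "NC" for v in rng.random(40) < 0.4]
        if len(set(labels)) < 2:
            labels[0], labels[1] = "C", "NC"
        a = roc_curve(scores, labels).auc
        b = roc_curve(-scores, labels).auc
        assert a == pytest.approx(1.0 - b)

    def test_null_distribution(self, rng):
        scores = rng.normal(size=2000)
        labels = ["C" if v else "NC" for v in rng.random(2000) < 0.5]
        assert roc_curve(scores, labels).auc == pytest.approx(0.5, abs=0.05)

    def test_monotone_sweep(self, rng):
        scores = rng.normal(size=50)
        labels = ["C" if v else "NC" for v in rng.random(50) < 0.5]
        res = roc_curve(scores, labels)
        assert np.all(np.diff(res.fpr) >= 0)
        assert np.all(np.diff(res.tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1.0, 2.0], ["NC", "NC"])


class TestRunSweep:
    def test_level_zero_equals_direct_baseline(self, small_cohort):
        report = run_sweep(
            small_cohort, "loss_distributed", levels=[0.1],
            n_realisations=2, master_seed=1,
        )
        direct = np.array([eg.sample_entropy(s).value for s in small_cohort])
        assert np.allclose(report.per_signal[0.0], direct)
        baseline_summary = report.summary(0.0)
        assert baseline_summary.rho_xy == 1.0
        _, p_direct = mann_whitney_u(
            direct[np.array(report.labels) == "NC"],
            direct[np.array(report.labels) == "C"],
        )
        assert baseline_summary.p_value == pytest.approx(p_direct)

    def test_deterministic_given_master_seed(self, small_cohort):
        kwargs = dict(levels=[0.2], n_realisations=2, master_seed=3)
        a = run_sweep(small_cohort, "loss_consecutive", **kwargs)
        b = run_sweep(small_cohort, "loss_consecutive", **kwargs)
        for lvl in a.per_signal:
            assert np.array_equal(a.per_signal[lvl], b.per_signal[lvl])

    def test_robust_flag_follows_threshold(self, small_cohort):
        report = run_sweep(
            small_cohort, "loss_distributed", levels=[0.05],
            n_realisations=2, master_seed=2,
        )
        for ls in report.levels:
            assert ls.robust == (ls.rho_xy > ROBUSTNESS_THRESHOLD)

    def test_loss_sweep_carries_linear_fit_and_roc(self, small_cohort):
        report = run_sweep(
            small_cohort, "loss_distributed", levels=[0.1, 0.3, 0.5],
            n_realisations=2, master_seed=4,
        )
        assert set(report.linear_fit) == {"NC", "C"}
        assert set(report.roc) == {0.0, 0.1, 0.3, 0.5}
        frame = report.to_frame()
        assert len(frame) == 2 * 4  # (levels incl. baseline) x classes

    def test_unlabelled_cohort_rejected(self, rng):
        sigs = [eg.Signal(rng.normal(size=50)) for _ in range(4)]
        with pytest.raises(ValueError):
            run_sweep(sigs, "spikes", levels=[0.1], n_realisations=1)
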