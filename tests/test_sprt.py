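"""Truncated SPRT: bounds, stopping-time thresholds, decision rules, baselines."""

import numpy as np
import pytest

from sprtbci import (
    FeatureSeries,
    StoppingThresholds,
    WaldThresholds,
    expected_stopping_time,
    fixed_time_baselines,
    optimize_stopping_time,
    run_sprt,
    run_sprt_batch,
    sequential_bayes,
    thresholds_from_stopping_time,
    wald_error_bounds,
)
from sprtbci.sprt import GaussianBayesClassifier

from test_model import features_from, make_model


class TestWaldBounds:
    def test_direct_substitution(self):
        assert wald_error_bounds(20.0, 0.05) == (0.05, 0.05)

    def test_vacuous_bound_clips_at_one(self):
        assert wald_error_bounds(1.0, 2.0) == (1.0, 1.0)

    def test_nonpositive_thresholds_rejected(self):
        with pytest.raises(ValueError):
            wald_error_bounds(-1.0, 0.1)
        with pytest.raises(ValueError):
            WaldThresholds(eta_L=0.5, eta_R=1.0)


class TestExpectedStoppingTime:
    def test_printed_formula_constant_sequence(self):
        # E[J|L] = 0.5, eta_L = e^2, eta_R = e^-2:
        # bound = (1 - e^-2) * 2 + e^-2 * (-2) ~ 1.4587 -> n = 3
        ej = np.full(20, 0.5)
        q_l, _ = expected_stopping_time(ej, -ej, np.e**2, np.e**-2)
        assert q_l == 3

    def test_zero_evidence_returns_inf_with_warning(self):
        with pytest.warns(RuntimeWarning, match="never crosses"):
            q_l, q_r = expected_stopping_time(
                np.zeros(10), np.zeros(10), np.e**2, np.e**-2
            )
        assert q_l == np.inf and q_r == np.inf

    def test_doubling_evidence_cannot_slow_stopping(self, rng):
        ej = rng.uniform(0.1, 1.0, size=30)
        q1, _ = expected_stopping_time(ej, -ej, 10.0, 0.1)
        q2, _ = expected_stopping_time(2 * ej, -2 * ej, 10.0, 0.1)
        assert q2 <= q1


class TestStoppingThresholds:
    @pytest.mark.parametrize(
        "ej_l,ej_r,q_e,xi_l,xi_r",
        [
            (np.full(20, 0.5), np.full(20, -0.5), 10, 5.0, -5.0),
            (np.full(20, 0.5), np.full(20, -0.25), 4, 2.0, -1.0),
            (0.1 * np.arange(1, 21), np.full(20, -0.1), 3, 0.6, -0.3),
        ],
    )
    def test_partial_sums(self, ej_l, ej_r, q_e, xi_l, xi_r):
        thr = thresholds_from_stopping_time(ej_l, ej_r, q_e)
        assert thr.xi_L == pytest.approx(xi_l)
        assert thr.xi_R == pytest.approx(xi_r)
        assert thr.q_E == q_e

    def test_out_of_range(self):
        with pytest.raises(ValueError, match="q_E"):
            thresholds_from_stopping_time(np.ones(5), -np.ones(5), 6)

    def test_monotone_widening_in_q_e(self):
        """On a well-fitted model the thresholds widen as q_E grows."""
        ej_l, ej_r = np.full(15, 0.4), np.full(15, -0.3)
        xs = [thresholds_from_stopping_time(ej_l, ej_r, q) for q in range(1, 16)]
        assert all(b.xi_L >= a.xi_L and b.xi_R <= a.xi_R for a, b in zip(xs, xs[1:]))


class TestRunSprt:
    def test_first_crossing(self):
        path = run_sprt(np.ones(10), StoppingThresholds(2.5, -2.5, 10))
        assert path.decision == "L"
        assert path.stop_segment == 3
        assert not path.forced
        np.testing.assert_allclose(path.trace, [1.0, 2.0, 3.0])

    def test_truncation_by_sign(self):
        j = np.array([0.4, -0.4, 0.4, -0.4, 0.4])
        path = run_sprt(j, StoppingThresholds(5.0, -5.0, 5))
        assert path.forced
        assert path.decision == "L"  # L_5 = 0.4 > 0
        assert path.stop_segment == 5

    def test_tie_policies(self):
        j = np.array([0.4, -0.4, 0.4, -0.4])
        thr = StoppingThresholds(5.0, -5.0, 4)
        path = run_sprt(j, thr, tie_policy="undecided")
        assert path.decision == "tie" and path.forced
        rng = np.random.default_rng(0)
        decisions = {
            run_sprt(j, thr, tie_policy="random", rng=rng).decision for _ in range(50)
        }
        assert decisions == {"L", "R"}

    def test_too_few_segments(self):
        with pytest.raises(ValueError, match="out of range"):
            run_sprt(np.ones(3), StoppingThresholds(1.0, -1.0, 5))

    def test_trace_additivity_and_interior(self, rng):
        """trace[q] = cumulative sum of J; interior stays between thresholds."""
        j = rng.normal(0.2, 1.0, size=30)
        thr = StoppingThresholds(3.0, -3.0, 30)
        path = run_sprt(j, thr, timestamps=np.arange(1.0, 31.0))
        np.testing.assert_allclose(path.trace, np.cumsum(j)[: path.stop_segment])
        if not path.forced:
            assert path.trace[-1] >= thr.xi_L or path.trace[-1] <= thr.xi_R
        assert np.all((path.trace[:-1] > thr.xi_R) & (path.trace[:-1] < thr.xi_L))
        assert path.stop_time == float(path.stop_segment)

    def test_empirical_errors_respect_wald_bounds(self, rng):
        """Monte-Carlo check of Wald's inequality on a known 1-D model."""
        n, q = 10_000, 80
        m = make_model([0.5], [[1.0]], [-0.5], [[1.0]], q=q)
        eta_l, eta_r = 19.0, 1 / 19.0
        xi_l, xi_r = np.log(eta_l), np.log(eta_r)
        for k, mean in [(0, 0.5), (1, -0.5)]:
            z = mean + rng.standard_normal((n, q, 1))
            j = m.log_pr_matrix(z)
            dec, _, forced, _ = run_sprt_batch(j, xi_l, xi_r, q, "random", rng)
            wrong = ("R", "L")[k]
            err = np.mean((dec == wrong) & ~forced)
            bound = (eta_r, 1 / eta_l)[k]
            tol = 2.33 * np.sqrt(bound * (1 - bound) / n)
            assert err <= bound + tol


class TestTruncationConsistency:
    def test_zero_thresholds_reduce_to_fixed_time_bayes(self, rng):
        """xi_L = xi_R = 0 decides every trial at q=1 by sign(J_1), which is
        the equal-prior Gaussian-Bayes decision at the first segment."""
        m = make_model([0.6, 0.4], 0.3 * np.eye(2), [0.4, 0.6], 0.3 * np.eye(2), q=4)
        vals = rng.gamma(2.0, size=(40, 4, 2))
        j = m.log_pr_matrix(vals)
        dec, stop, forced, _ = run_sprt_batch(j, 0.0, 0.0, 4, "random", rng)
        assert np.all(stop == 1)
        assert not forced.any()
        expected = np.where(j[:, 0] > 0, "L", "R")
        assert np.all(dec == expected)


class TestSequentialBayes:
    def test_flat_prior_trace_equals_sprt_evidence(self, rng):
        m = make_model([0.6, 0.4], 0.3 * np.eye(2), [0.4, 0.6], 0.3 * np.eye(2), q=5)
        vals = rng.gamma(2.0, size=(10, 5, 2))
        labels = np.array(["L", "R"] * 5, dtype=object)
        res = sequential_bayes(features_from(vals, labels), m)
        np.testing.assert_allclose(res.odds, np.cumsum(m.log_pr_matrix(vals), axis=1))

    def test_certain_prior_always_decides_that_class(self, rng):
        m = make_model([0.6], [[0.1]], [0.4], [[0.1]], q=3)
        vals = rng.gamma(2.0, size=(6, 3, 1))
        res = sequential_bayes(features_from(vals), m, priors=(1.0, 0.0), decision_index=3)
        assert np.all(res.decisions == "L")

    def test_invalid_priors(self, rng):
        m = make_model([0.6], [[0.1]], [0.4], [[0.1]])
        vals = rng.gamma(2.0, size=(4, 1, 1))
        with pytest.raises(ValueError, match="priors"):
            sequential_bayes(features_from(vals), m, priors=(-0.5, 1.5))

    def test_decision_index_selected_on_labelled_data(self, rng):
        # separation grows with segment index, so later indices are preferred
        from sprtbci import SegmentGaussianModel

        q = 6
        means_l = np.linspace(0.1, 2.0, q)[:, None]
        m = SegmentGaussianModel(
            means=np.stack([means_l, -means_l]),
            covs=np.tile(np.eye(1), (2, q, 1, 1)),
        )
        n = 200
        vals = np.stack(
            [means_l[:, 0] + rng.standard_normal(q) for _ in range(n)]
            + [-means_l[:, 0] + rng.standard_normal(q) for _ in range(n)]
        )[..., None]
        labels = np.array(["L"] * n + ["R"] * n, dtype=object)
        res = sequential_bayes(features_from(vals, labels), m)
        assert res.decision_index >= q - 2


class TestStoppingTimeOptimization:
    def _features(self, rng, n=60, q=12, gap=0.8):
        half = np.linspace(0.2, gap, q)
        vals = np.concatenate(
            [half + rng.standard_normal((n, q)), -half + rng.standard_normal((n, q))]
        )[..., None]
        labels = np.array(["L"] * n + ["R"] * n, dtype=object)
        return features_from(vals, labels)

    def test_singleton_grid(self, rng):
        feats = self._features(rng)
        res = optimize_stopping_time(feats, [5], criterion="smi", seed=0)
        assert res.q_opt == 5 and res.thresholds.q_E == 5

    def test_empty_grid(self, rng):
        with pytest.raises(ValueError, match="empty"):
            optimize_stopping_time(self._features(rng), [], seed=0)

    def test_accuracy_curve_non_decreasing_on_easy_data(self, rng):
        feats = self._features(rng, n=150, gap=1.0)
        res = optimize_stopping_time(feats, [1, 3, 6, 9, 12], criterion="accuracy", seed=0)
        assert np.all(np.diff(res.accuracy) >= -0.03)

    def test_smi_prefers_earlier_stopping_than_accuracy(self, rng):
        """When the accuracy curve plateaus, the time penalty in SMI picks a
        strictly smaller stopping target."""
        feats = self._features(rng, n=200, gap=2.5)  # saturates early
        grid = [1, 2, 4, 8, 12]
        res_acc = optimize_stopping_time(feats, grid, criterion="accuracy", seed=0)
        res_smi = optimize_stopping_time(feats, grid, criterion="smi", seed=0)
        assert res_smi.q_opt < max(grid)
        assert res_smi.q_opt <= res_acc.q_opt

    def test_mean_decision_time_criterion_respects_floor(self, rng):
        feats = self._features(rng, n=150, gap=1.5)
        res = optimize_stopping_time(
            feats, [2, 6, 12], criterion="mean_decision_time", accuracy_floor=0.6, seed=0
        )
        sel = list(res.q_grid).index(res.q_opt)
        assert res.accuracy[sel] >= 0.6


class TestFixedTimeBaselines:
    def test_separated_clouds_are_perfectly_fit(self, rng):
        x = np.concatenate([rng.normal(5, 0.1, (20, 2)), rng.normal(-5, 0.1, (20, 2))])
        y = np.array(["L"] * 20 + ["R"] * 20, dtype=object)
        for kind in ("gaussian_bayes", "lda"):
            _, pred = fixed_time_baselines(x, y, kind=kind)
            assert np.all(pred == y)

    def test_gaussian_bayes_equals_sign_of_log_pr(self, rng):
        x = np.concatenate([rng.normal(0.5, 1, (50, 2)), rng.normal(-0.5, 1, (50, 2))])
        y = np.array(["L"] * 50 + ["R"] * 50, dtype=object)
        clf, pred = fixed_time_baselines(x, y, kind="gaussian_bayes")
        m = make_model(clf.means_[0], clf.covs_[0], clf.means_[1], clf.covs_[1])
        expected = np.array(
            ["L" if m.log_pr(v, 0) >= 0 else "R" for v in x], dtype=object
        )
        assert np.all(pred == expected)

    def test_singular_covariance_advises_shrinkage(self):
        x = np.tile([[1.0, 2.0]], (10, 1))
        y = np.array(["L", "R"] * 5, dtype=object)
        with pytest.raises(ValueError, match="shrinkage"):
            GaussianBayesClassifier(shrinkage=0.0).fit(x, y)

    def test_unknown_kind(self, rng):
        with pytest.raises(ValueError, match="kind"):
            fixed_time_baselines(rng.normal(size=(8, 2)), np.array(["L", "R"] * 4), kind="svm")
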