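"""Projective-base extraction: GEVD congruences, branch selection, powers."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings
from hypothesis import strategies as st

from sprtbci import (
    SegmentationScheme,
    autocorrelation,
    extract_features,
    fit_bases,
    generate_dataset,
    power_ratio,
    projective_power,
    select_basis,
    simultaneous_diagonalization,
)
from sprtbci.features import ProjectiveBasis


def random_spd(rng, m, scale=1.0):
    a = rng.standard_normal((m, m))
    return a @ a.T / m + scale * np.eye(m)


class TestAutocorrelation:
    def test_single_vector_outer_product(self):
        np.testing.assert_array_equal(
            autocorrelation(np.array([[1.0, 0.0]])), [[1.0, 0.0], [0.0, 0.0]]
        )

    def test_two_vector_average_is_identity(self):
        x = np.array([[1.0, 1.0], [1.0, -1.0]])
        np.testing.assert_allclose(autocorrelation(x), np.eye(2))

    def test_gram_structure_is_psd(self, rng):
        x = rng.standard_normal((7, 5))
        r = autocorrelation(x, ridge=0.3)
        assert np.all(np.linalg.eigvalsh(r - 0.3 * np.eye(5)) >= -1e-10)
        np.testing.assert_array_equal(r, r.T)

    def test_errors(self):
        with pytest.raises(ValueError, match="at least one"):
            autocorrelation(np.empty((0, 3)))
        with pytest.raises(ValueError, match="non-finite"):
            autocorrelation(np.array([[np.inf, 0.0]]))


class TestSimultaneousDiagonalization:
    def test_already_diagonal(self):
        t, lam = simultaneous_diagonalization(np.diag([4.0, 1.0]), np.eye(2))
        np.testing.assert_allclose(lam, [4.0, 1.0])
        np.testing.assert_allclose(np.abs(t), np.eye(2), atol=1e-12)

    def test_equal_matrices_give_unit_eigenvalues(self, rng):
        r = random_spd(rng, 5)
        _, lam = simultaneous_diagonalization(r, r)
        np.testing.assert_allclose(lam, np.ones(5), atol=1e-10)

    def test_congruences_on_random_pairs(self, rng):
        """T' R_L T = diag(lambda) and T' R_R T = I, direct matrix oracle."""
        for _ in range(5):
            r_l, r_r = random_spd(rng, 6), random_spd(rng, 6)
            t, lam = simultaneous_diagonalization(r_l, r_r)
            assert np.all(np.diff(lam) <= 1e-12)
            num = np.linalg.norm(t.T @ r_l @ t - np.diag(lam))
            assert num / np.linalg.norm(np.diag(lam)) < 1e-8
            assert np.linalg.norm(t.T @ r_r @ t - np.eye(6)) < 1e-8

    def test_extremal_property_against_random_probes(self, rng):
        """lambda_M <= F(w) <= lambda_1 for random unit w; endpoints attained."""
        r_l, r_r = random_spd(rng, 6), random_spd(rng, 6)
        t, lam = simultaneous_diagonalization(r_l, r_r)
        w = rng.standard_normal((200, 6))
        w /= np.linalg.norm(w, axis=1, keepdims=True)
        f = np.array([power_ratio(v, r_l, r_r) for v in w])
        assert np.all(f <= lam[0] + 1e-8)
        assert np.all(f >= lam[-1] - 1e-8)
        u_max = t[:, 0] / np.linalg.norm(t[:, 0])
        assert power_ratio(u_max, r_l, r_r) >= f.max() - 1e-8

    def test_scale_invariance_of_objective(self, rng):
        r_l, r_r = random_spd(rng, 4), random_spd(rng, 4)
        u = rng.standard_normal(4)
        assert np.isclose(power_ratio(u, r_l, r_r), power_ratio(-2.7 * u, r_l, r_r))


class TestSelectBasis:
    @pytest.mark.parametrize(
        "lam,branch,col",
        [
            ((4.0, 1.0), "max", 0),  # 4 > 1/1
            ((1.2, 0.1), "min", -1),  # 1/0.1 = 10 > 1.2
            ((2.0, 0.5), "max", 0),  # exact tie goes to the max branch
        ],
    )
    def test_branch_rule(self, lam, branch, col):
        t = np.array([[2.0, 0.0], [0.0, 3.0]])
        basis = select_basis(t, np.asarray(lam))
        assert basis.branch == branch
        expected = t[:, col] / np.linalg.norm(t[:, col])
        np.testing.assert_allclose(np.abs(basis.u), np.abs(expected))
        assert np.isclose(np.linalg.norm(basis.u), 1.0)

    def test_nonpositive_eigenvalue_rejected(self):
        with pytest.raises(ValueError, match="not positive"):
            select_basis(np.eye(2), np.array([1.0, 0.0]))

    def test_selected_basis_attains_its_eigenvalue(self, rng):
        """F(u) evaluated on the training pair equals the chosen eigenvalue."""
        r_l, r_r = random_spd(rng, 5), random_spd(rng, 5)
        t, lam = simultaneous_diagonalization(r_l, r_r)
        basis = select_basis(t, lam)
        target = lam[0] if basis.branch == "max" else lam[-1]
        assert abs(power_ratio(basis.u, r_l, r_r) - target) < 1e-8 * abs(target)

    def test_unit_norm_enforced(self):
        with pytest.raises(ValueError, match="unit norm"):
            ProjectiveBasis(u=np.array([2.0, 0.0]), lambda_max=1, lambda_min=1, branch="max")


class TestProjectivePower:
    def test_hand_examples(self):
        assert projective_power([1.0, 0.0], [3.0, 4.0]) == 9.0
        assert projective_power([1.0, 0.0], [0.0, 5.0]) == 0.0

    def test_matches_outer_product_oracle(self, rng):
        u = rng.standard_normal(32)
        x = rng.standard_normal(32)
        oracle = u @ np.outer(x, x) @ u
        assert np.isclose(projective_power(u, x), oracle, rtol=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            projective_power([1.0, 0.0], [1.0, 0.0, 0.0])

    @settings(derandomize=True, max_examples=30)
    @given(c=st.floats(min_value=-10, max_value=10, allow_nan=False))
    def test_quadratic_scaling(self, c):
        u = np.array([0.6, 0.8])
        x = np.array([1.5, -2.0])
        assert np.isclose(projective_power(u, c * x), c**2 * projective_power(u, x))


class TestFitBases:
    def test_class_swap_inverts_the_ratio(self, quick_dataset):
        epochs, _ = quick_dataset
        swapped = epochs.subset(np.arange(epochs.n_trials))
        swapped.labels = np.where(epochs.labels == "L", "R", "L").astype(object)
        scheme = SegmentationScheme()
        a = fit_bases(epochs, scheme, ridge=1e-8)
        b = fit_bases(swapped, scheme, ridge=1e-8)
        for ch in ("C3", "C4"):
            # same extremal filter up to sign, opposite branch, reciprocal ratio
            assert abs(abs(a[ch].u @ b[ch].u) - 1.0) < 1e-6
            lam_a = a[ch].lambda_max if a[ch].branch == "max" else a[ch].lambda_min
            lam_b = b[ch].lambda_max if b[ch].branch == "max" else b[ch].lambda_min
            assert np.isclose(lam_a * lam_b, 1.0, rtol=1e-6)

    def test_identical_channels_get_identical_bases(self, quick_config):
        cfg = replace(
            quick_config,
            erd_depth={("R", "C3", "mu"): 0.4, ("R", "C4", "mu"): 0.4},
            seed=31,
        )
        epochs, _ = generate_dataset(cfg)
        epochs.data[:, 1, :] = epochs.data[:, 0, :]
        bases = fit_bases(epochs, SegmentationScheme())
        np.testing.assert_allclose(bases["C3"].u, bases["C4"].u, atol=1e-10)

    def test_missing_channel_is_reported(self, quick_dataset):
        epochs, _ = quick_dataset
        with pytest.raises(KeyError, match="Cz"):
            fit_bases(epochs, SegmentationScheme(), channels=("C3", "Cz"))

    def test_unlabelled_epochs_rejected(self, quick_dataset):
        epochs, _ = quick_dataset
        unlabelled = epochs.subset(np.arange(epochs.n_trials))
        unlabelled.labels = None
        with pytest.raises(ValueError, match="label"):
            fit_bases(unlabelled, SegmentationScheme())


class TestExtractFeatures:
    def test_zero_signal_gives_zero_features(self, quick_dataset):
        epochs, _ = quick_dataset
        scheme = SegmentationScheme()
        bases = fit_bases(epochs, scheme)
        silent = epochs.subset([0, 1])
        silent.data = np.zeros_like(silent.data)
        feats = extract_features(silent, scheme, bases)
        np.testing.assert_array_equal(feats.values, 0.0)

    def test_quadratic_in_signal_scale(self, quick_dataset):
        epochs, _ = quick_dataset
        scheme = SegmentationScheme()
        bases = fit_bases(epochs, scheme)
        doubled = epochs.subset(np.arange(4))
        doubled.data = doubled.data * 2.0
        f1 = extract_features(epochs.subset(np.arange(4)), scheme, bases)
        f2 = extract_features(doubled, scheme, bases)
        np.testing.assert_allclose(f2.values, 4.0 * f1.values, rtol=1e-10)

    def test_feature_counts_and_nonnegativity(self, quick_dataset):
        epochs, _ = quick_dataset
        scheme = SegmentationScheme()
        bases = fit_bases(epochs, scheme)
        feats = extract_features(epochs, scheme, bases)
        from sprtbci import segment_trials

        seg = segment_trials(epochs, scheme)
        assert feats.values.shape == (epochs.n_trials, seg.data.shape[1], 2)
        assert np.all(feats.values >= 0)
        np.testing.assert_array_equal(feats.timestamps, seg.timestamps)

    def test_wrong_window_length_rejected(self, quick_dataset):
        epochs, _ = quick_dataset
        bases = fit_bases(epochs, SegmentationScheme())
        with pytest.raises(ValueError, match="window"):
            extract_features(epochs, SegmentationScheme(window_length=2.0, step=0.25), bases)


class TestErdSignature:
    def test_suppressed_class_has_lower_post_cue_power(self, quick_dataset):
        """Planted ERD shows up as a class difference in projected power."""
        import scipy.stats

        epochs, _ = quick_dataset  # R-class mu suppressed on C3
        scheme = SegmentationScheme()
        bases = fit_bases(epochs, scheme)
        feats = extract_features(epochs, scheme, bases)
        post = feats.restrict(epochs.cue_time + scheme.window_length)
        e_c3 = post.values[:, :, 0].mean(axis=1)
        lo = e_c3[epochs.labels == "R"]
        hi = e_c3[epochs.labels == "L"]
        stat = scipy.stats.mannwhitneyu(lo, hi, alternative="less")
        assert stat.pvalue < 0.01
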