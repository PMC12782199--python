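import hashlib

import numpy as np
import pytest
import scipy.linalg

from ssvepipe.rca import (
    CovariancePair,
    component_topography,
    compute_covariances,
    fit_rca,
    project,
    project_spectra,
)
from ssvepipe.spectral import SpectraSet
from ssvepipe.experiments import rca_recovery_experiment


def _obs(rng, n_trials, n_obs, n_ch, source_topo=None, source_sd=1.0, noise_sd=1.0, shared=None):
    """Trials = shared(consistent) source × topography + independent noise."""
    xs = []
    for _ in range(n_trials):
        x = noise_sd * rng.normal(size=(n_obs, n_ch))
        if source_topo is not None:
            x += np.outer(shared, source_topo)
        xs.append(x)
    return xs


class TestCovariances:
    def test_identical_trials_give_equal_covariances(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(40, 5))
        cov = compute_covariances([[x.copy() for _ in range(4)]])
        np.testing.assert_allclose(cov.r_xy, cov.r_xx, atol=1e-10)

    def test_independent_noise_has_small_cross_covariance(self):
        """Cross-trial covariance of independent noise → 0 (Monte-Carlo)."""
        rng = np.random.default_rng(1)
        xs = [rng.normal(size=(20, 4)) for _ in range(1000)]
        cov = compute_covariances([xs])
        ratio = np.linalg.norm(cov.r_xy) / np.linalg.norm(cov.r_xx)
        assert ratio < 0.1

    def test_two_channel_brute_force(self):
        """Pooled covariances match an explicit pairwise computation."""
        rng = np.random.default_rng(2)
        xs = [rng.normal(size=(6, 2)) for _ in range(3)]
        cov = compute_covariances([xs])
        mean = np.mean([x.mean(axis=0) for x in xs], axis=0)
        cs = [x - mean for x in xs]
        rxx = sum(c.T @ c for c in cs) / (3 * 6)
        rxy = sum(cs[i].T @ cs[j] for i in range(3) for j in range(3) if i != j) / (6 * 6)
        rxy = 0.5 * (rxy + rxy.T)
        np.testing.assert_allclose(cov.r_xx, rxx, atol=1e-12)
        np.testing.assert_allclose(cov.r_xy, rxy, atol=1e-12)

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            compute_covariances([[np.zeros((4, 3))]])


class TestFitRCA:
    def test_planted_source_recovery(self):
        res = rca_recovery_experiment(seed=11, n_runs=5)
        assert res["successes"] == 5

    def test_more_reliable_source_ranks_first(self):
        """Two planted sources with different cross-trial consistency: RC1
        matches the more reliable one."""
        rng = np.random.default_rng(3)
        n_obs, n_ch, n_trials = 30, 8, 40
        v1 = np.zeros(n_ch); v1[0] = 1.0
        v2 = np.zeros(n_ch); v2[4] = 1.0
        s1 = rng.normal(size=n_obs)  # fully consistent across trials
        xs = []
        for _ in range(n_trials):
            s2 = rng.normal(size=n_obs)  # redrawn per trial → unreliable
            xs.append(np.outer(s1, v1) + 2.0 * np.outer(s2, v2) + 0.1 * rng.normal(size=(n_obs, n_ch)))
        model = fit_rca(compute_covariances([xs]), n_components=2)
        assert np.argmax(np.abs(model.W[:, 0])) == 0

    def test_signal_channel_has_max_weight(self):
        rng = np.random.default_rng(4)
        n_obs, n_ch = 25, 6
        v = np.zeros(n_ch); v[0] = 1.0
        s = rng.normal(size=n_obs)
        xs = [np.outer(s, v) + 0.3 * rng.normal(size=(n_obs, n_ch)) for _ in range(30)]
        model = fit_rca(compute_covariances([xs]), n_components=2)
        assert np.argmax(np.abs(model.W[:, 0])) == 0
        assert model.W[np.argmax(np.abs(model.W[:, 0])), 0] > 0  # sign convention

    def test_matches_brute_force_whitened_eigensolution(self):
        rng = np.random.default_rng(5)
        xs = [rng.normal(size=(12, 4)) + np.outer(np.ones(12), rng.normal(size=4)) for _ in range(6)]
        cov = compute_covariances([xs])
        model = fit_rca(cov, n_components=4, regularization=1e-3)
        # explicit whitening: R_xx^{-1/2} R_xy R_xx^{-1/2}
        load = 1e-3 * np.trace(cov.r_xx) / 4
        rxx = cov.r_xx + load * np.eye(4)
        w_half = scipy.linalg.fractional_matrix_power(rxx, -0.5).real
        evals = np.sort(np.linalg.eigvalsh(w_half @ cov.r_xy @ w_half))[::-1]
        np.testing.assert_allclose(np.sort(model.eigenvalues)[::-1], evals, atol=1e-8)

    def test_k_exceeding_channels_rejected(self):
        cov = CovariancePair(np.eye(3), np.eye(3), 2, 10)
        with pytest.raises(ValueError):
            fit_rca(cov, n_components=4)

    def test_eigenvalues_descending_and_deterministic(self):
        rng = np.random.default_rng(6)
        xs = [rng.normal(size=(10, 5)) for _ in range(5)]
        cov = compute_covariances([xs])
        m1 = fit_rca(cov, n_components=5)
        m2 = fit_rca(cov, n_components=5)
        assert (np.diff(m1.eigenvalues) <= 1e-12).all()
        np.testing.assert_array_equal(m1.W, m2.W)


class TestProjection:
    def test_identity_column_selects_channel(self):
        n_ch = 4
        w = np.zeros((n_ch, 1)); w[0, 0] = 1.0
        model_like = type("M", (), {"W": w, "n_components": 1})()
        coefs = np.random.default_rng(0).normal(size=(3, n_ch, 2, 5)) * (1 + 1j)
        out = project(coefs, model_like)
        np.testing.assert_allclose(out[:, 0], coefs[:, 0])

    def test_linearity(self):
        n_ch = 6
        w = np.random.default_rng(1).normal(size=(n_ch, 3))
        model_like = type("M", (), {"W": w, "n_components": 3})()
        coefs = np.random.default_rng(2).normal(size=(2, n_ch, 4, 3)).astype(complex)
        np.testing.assert_allclose(project(2 * coefs, model_like), 2 * project(coefs, model_like))

    def test_dimension_mismatch(self):
        w = np.ones((5, 2))
        model_like = type("M", (), {"W": w, "n_components": 2})()
        with pytest.raises(ValueError):
            project(np.zeros((1, 4, 2, 2), dtype=complex), model_like)

    def test_component_validity_requires_all_channels(self):
        w = np.ones((3, 2))
        model_like = type("M", (), {"W": w, "n_components": 2})()
        s = SpectraSet(
            "S1", "OD", "ON",
            coefs=np.ones((1, 3, 2, 4), dtype=complex),
            valid=np.ones((1, 4, 3), dtype=bool),
        )
        s.valid[0, 2, 1] = False  # one bad channel in bin 2
        out = project_spectra(s, model_like)
        assert not out.valid[0, 2].any()
        assert out.valid[0, 0].all()


class TestTopography:
    def test_identity_covariance_orthonormal_w(self):
        q, _ = np.linalg.qr(np.random.default_rng(0).normal(size=(6, 3)))
        a = component_topography(q, np.eye(6))
        np.testing.assert_allclose(a, q, atol=1e-12)

    def test_column_rescaling_only_rescales_columns(self):
        """Rescaling W's columns by d rescales A's columns by 1/d: the pattern
        directions are invariant (A·D⁻¹ = R·WD·(DWᵀRWD)⁻¹)."""
        rng = np.random.default_rng(1)
        w = rng.normal(size=(5, 2))
        rxx = np.cov(rng.normal(size=(5, 100)))
        a1 = component_topography(w, rxx)
        a2 = component_topography(w * np.array([3.0, -0.5]), rxx)
        np.testing.assert_allclose(a2, a1 * np.array([1 / 3.0, -2.0]), atol=1e-10)

    def test_group_blindness(self):
        """Weights depend on control data only: adding patient data to the
        projection step cannot change W (hash check)."""
        rng = np.random.default_rng(2)
        xs = [rng.normal(size=(10, 4)) for _ in range(5)]
        cov = compute_covariances([xs])
        model = fit_rca(cov, n_components=2)
        h_before = hashlib.sha256(model.W.tobytes()).hexdigest()
        patient_coefs = rng.normal(size=(3, 4, 2, 2)).astype(complex)
        project(patient_coefs, model)
        assert hashlib.sha256(model.W.tobytes()).hexdigest() == h_before
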