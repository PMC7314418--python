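"""Decoder core: oracle equivalences, shrinkage properties, smoothing."""

import numpy as np
import pytest
from scipy import stats
from sklearn.covariance import LedoitWolf

from vdac import EpochSet, crossval_distance_decode, fit_pca_reduce, mahalanobis
from vdac.decoding import (
    CovarianceModel,
    DecodingTimecourse,
    fit_class_models,
    gaussian_kernel,
    ledoit_wolf_timecourse,
    shrinkage_covariance,
    smooth_timecourse,
)


def _epochs_from_array(data, sfreq=250.0):
    n, c, t = data.shape
    times = np.arange(t) * 1000.0 / sfreq
    return EpochSet(data=data, times_ms=times, sfreq_hz=sfreq,
                    channel_ids=[f"ch{i}" for i in range(c)])


class TestMahalanobis:
    def test_identity_covariance_reduces_to_euclidean(self):
        cov = CovarianceModel(np.eye(2), np.eye(2), 0.0)
        assert mahalanobis([3.0, 4.0], [0.0, 0.0], cov) == pytest.approx(5.0)

    def test_diagonal_closed_form(self):
        cov = CovarianceModel(np.diag([4.0, 1.0]), np.diag([0.25, 1.0]), 0.0)
        assert mahalanobis([2.0, 1.0], [0.0, 0.0], cov) == pytest.approx(np.sqrt(2.0))

    def test_matches_bruteforce_quadratic_form(self, rng):
        """100 random instances vs explicit inverse-then-quadratic-form."""
        for _ in range(100):
            f = rng.integers(2, 8)
            A = rng.standard_normal((f, f))
            S = A @ A.T + f * np.eye(f)
            cov = CovarianceModel(S, np.linalg.inv(S), 0.0)
            x = rng.standard_normal(f)
            mu = rng.standard_normal(f)
            expected = np.sqrt((x - mu) @ np.linalg.inv(S) @ (x - mu))
            assert mahalanobis(x, mu, cov) == pytest.approx(expected, abs=1e-10)

    def test_dimension_mismatch_rejected(self):
        cov = CovarianceModel(np.eye(2), np.eye(2), 0.0)
        with pytest.raises(ValueError, match="dimension"):
            mahalanobis([1.0, 2.0, 3.0], [0.0, 0.0], cov)


class TestShrinkageCovariance:
    def test_forced_full_shrinkage_equals_diagonal_target(self, rng):
        X = rng.standard_normal((20, 5))
        model = shrinkage_covariance(X, shrinkage=1.0)
        Xc = X - X.mean(axis=0)
        S = Xc.T @ Xc / 20
        target = (np.trace(S) / 5) * np.eye(5)
        assert np.allclose(model.covariance, target)

    def test_large_n_approaches_sample_covariance(self, rng):
        X = rng.standard_normal((5000, 4)) @ np.diag([1.0, 2.0, 0.5, 1.5])
        model = shrinkage_covariance(X)
        Xc = X - X.mean(axis=0)
        S = Xc.T @ Xc / X.shape[0]
        rel = np.linalg.norm(model.covariance - S) / np.linalg.norm(S)
        assert rel < 0.05 and model.shrinkage_intensity < 0.05

    def test_positive_definite_when_features_exceed_observations(self, rng):
        X = rng.standard_normal((6, 20))
        model = shrinkage_covariance(X)
        assert np.linalg.eigvalsh(model.covariance).min() > 0
        assert np.allclose(model.inverse @ model.covariance, np.eye(20), atol=1e-8)

    def test_matches_sklearn_ledoit_wolf(self, rng):
        X = rng.standard_normal((40, 6)) @ np.diag([3, 1, 1, 0.5, 2, 1.0])
        model = shrinkage_covariance(X)
        lw = LedoitWolf().fit(X)
        assert model.shrinkage_intensity == pytest.approx(lw.shrinkage_, abs=1e-10)
        assert np.allclose(model.covariance, lw.covariance_, atol=1e-10)

    def test_vectorised_timecourse_matches_scalar_estimator(self, rng):
        X = rng.standard_normal((15, 4, 3))
        cov, prec, lam = ledoit_wolf_timecourse(X - X.mean(axis=0))
        for t in range(3):
            ref = shrinkage_covariance(X[:, :, t])
            assert lam[t] == pytest.approx(ref.shrinkage_intensity, abs=1e-12)
            assert np.allclose(cov[t], ref.covariance, atol=1e-12)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="n_obs"):
            shrinkage_covariance(np.ones((1, 3)))


class TestPcaReduce:
    def test_rank_limit_caps_components(self, rng):
        # rank-5 data embedded in 12 channels
        basis = rng.standard_normal((5, 12))
        scores = rng.standard_normal((30, 6, 5))
        data = np.transpose(scores @ basis, (0, 2, 1))
        red = fit_pca_reduce(_epochs_from_array(data), n_components=70)
        assert red.n_channels == 5
        assert red.explained_variance_ratio_.sum() == pytest.approx(1.0, abs=1e-9)

    def test_rotation_invariance_of_delta(self, rng):
        """An orthogonal channel rotation leaves decoding unchanged."""
        n, c, t = 24, 6, 4
        data = rng.standard_normal((n, c, t))
        labels = np.repeat([0, 1], n // 2)
        data[labels == 1, 0] += 1.5
        Q, _ = np.linalg.qr(rng.standard_normal((c, c)))
        rotated = np.einsum("dc,nct->ndt", Q, data)
        tc_a = crossval_distance_decode(
            fit_pca_reduce(_epochs_from_array(data), c), labels, k=4, repeats=3, seed=0)
        tc_b = crossval_distance_decode(
            fit_pca_reduce(_epochs_from_array(rotated), c), labels, k=4, repeats=3, seed=0)
        assert np.allclose(tc_a.delta, tc_b.delta, atol=1e-8)

    def test_invalid_component_count_rejected(self, rng):
        with pytest.raises(ValueError, match="n_components"):
            fit_pca_reduce(_epochs_from_array(rng.standard_normal((5, 3, 2))), 0)


class TestCrossvalDecode:
    def test_shuffled_labels_give_chance_level(self, rng):
        n, c, t = 60, 8, 10
        data = rng.standard_normal((n, c, t))
        labels = rng.permutation(np.repeat([0, 1], n // 2))
        tc = crossval_distance_decode(_epochs_from_array(data), labels,
                                      k=5, repeats=5, seed=0)
        grand = tc.delta.mean()
        sem = tc.delta.mean(axis=1).std(ddof=1) / np.sqrt(n)
        assert abs(grand) < 2 * sem + 1e-12 or abs(grand) < 0.05

    def test_planted_separation_positive_everywhere(self, rng):
        n, c, t = 40, 6, 5
        labels = np.repeat([0, 1], n // 2)
        data = 0.05 * rng.standard_normal((n, c, t))
        data[labels == 1, 0] += 4.0
        tc = crossval_distance_decode(_epochs_from_array(data), labels,
                                      k=5, repeats=3, seed=1)
        assert (tc.delta > 0).all()

    def test_leave_one_out_matches_bruteforce_oracle(self, rng):
        """k = n on a 6-trial toy set vs a hand-rolled LOO computation."""
        from vdac.decoding import _lw_from_demeaned

        n, c = 6, 3
        data = rng.standard_normal((n, c, 2))
        labels = np.array([0, 0, 0, 1, 1, 1])
        tc = crossval_distance_decode(_epochs_from_array(data), labels,
                                      k=n, repeats=1, seed=0)
        expected = np.zeros((n, 2))
        for i in range(n):
            tr = np.delete(np.arange(n), i)
            for t in range(2):
                Xtr, ytr = data[tr, :, t], labels[tr]
                mu = {c_: Xtr[ytr == c_].mean(axis=0) for c_ in (0, 1)}
                resid = np.vstack([Xtr[ytr == c_] - mu[c_] for c_ in (0, 1)])
                Scov, _lam = _lw_from_demeaned(resid)
                P = np.linalg.inv(Scov)
                x = data[i, :, t]
                own, other = mu[labels[i]], mu[1 - labels[i]]
                d_own = np.sqrt((x - own) @ P @ (x - own))
                d_other = np.sqrt((x - other) @ P @ (x - other))
                expected[i, t] = d_other - d_own
        assert np.allclose(tc.delta, expected, atol=1e-10)

    def test_scale_invariance_of_delta(self, rng):
        n, c, t = 30, 5, 4
        data = rng.standard_normal((n, c, t))
        labels = np.repeat([0, 1], n // 2)
        data[labels == 1] += 0.5
        tc_a = crossval_distance_decode(_epochs_from_array(data), labels,
                                        k=5, repeats=2, seed=3)
        tc_b = crossval_distance_decode(_epochs_from_array(7.5 * data), labels,
                                        k=5, repeats=2, seed=3)
        assert np.allclose(tc_a.delta, tc_b.delta, atol=1e-8)

    def test_delta_monotone_in_signal_amplitude(self, rng):
        n, c, t = 40, 6, 3
        labels = np.repeat([0, 1], n // 2)
        noise = rng.standard_normal((n, c, t))
        amplitudes = [0.0, 0.5, 1.0, 2.0, 4.0]
        means = []
        for a in amplitudes:
            data = noise.copy()
            data[labels == 1, 0] += a
            tc = crossval_distance_decode(_epochs_from_array(data), labels,
                                          k=5, repeats=2, seed=4)
            means.append(tc.delta.mean())
        assert stats.spearmanr(amplitudes, means).statistic > 0.95

    def test_train_test_separation(self, rng):
        """Mutating held-out trials never changes the fitted class models."""
        n, c, t = 20, 4, 3
        data = rng.standard_normal((n, c, t))
        labels = np.repeat([0, 1], n // 2)
        train_idx = np.arange(15)
        means_a, prec_a, _ = fit_class_models(data[train_idx], labels[train_idx])
        data_mut = data.copy()
        data_mut[15:] += 100.0
        means_b, prec_b, _ = fit_class_models(data_mut[train_idx], labels[train_idx])
        assert np.array_equal(means_a, means_b)
        assert np.array_equal(prec_a, prec_b)

    def test_class_below_k_rejected(self, rng):
        data = rng.standard_normal((8, 3, 2))
        labels = np.array([0, 0, 0, 0, 0, 1, 1, 1])
        with pytest.raises(ValueError, match="'1'|1"):
            crossval_distance_decode(_epochs_from_array(data), labels, k=5)


class TestSmoothing:
    def _tc(self, delta, sfreq=250.0):
        t = delta.shape[1]
        return DecodingTimecourse(delta=delta, trial_index=np.arange(len(delta)),
                                  times_ms=np.arange(t) * 1000 / sfreq,
                                  sfreq_hz=sfreq)

    def test_sigma_zero_is_identity(self, rng):
        tc = self._tc(rng.standard_normal((4, 30)))
        out = smooth_timecourse(tc, 0.0)
        assert np.array_equal(out.delta, tc.delta)

    def test_constant_timecourse_unchanged(self):
        tc = self._tc(np.full((3, 50), 2.5))
        out = smooth_timecourse(tc, 16.0)
        assert np.allclose(out.delta, 2.5, atol=1e-12)

    def test_impulse_response_is_sampled_gaussian(self):
        n_t = 101
        delta = np.zeros((1, n_t))
        delta[0, 50] = 1.0
        out = smooth_timecourse(self._tc(delta), 16.0)
        kernel = gaussian_kernel(16.0, 250.0)
        half = len(kernel) // 2
        assert np.allclose(out.delta[0, 50 - half:50 + half + 1], kernel, atol=1e-12)

    def test_negative_sigma_rejected(self, rng):
        with pytest.raises(ValueError, match="sigma"):
            smooth_timecourse(self._tc(np.zeros((1, 5))), -1.0)
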