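import numpy as np
import pytest
from scipy.stats import multivariate_normal

from neurogeom import synthdata
from neurogeom.dataset import LabeledDataset, LabelMeta
from neurogeom.gkr import (
    CovKernelModel,
    GKRModel,
    fit_cov_kernel,
    fit_gkr,
    fit_gkrs,
    gkr_loglik,
    gkrs_moments,
    gkrs_resample,
    silverman_bandwidths,
)
from neurogeom.gp import fit_mean_gp


def _bank(T=40, N=3, M=2, seed=0, resid_scale=1.0):
    rng = np.random.default_rng(seed)
    Xi = rng.uniform(0, 1, (T, M))
    resid = resid_scale * rng.standard_normal((T, N))
    return Xi, resid


class TestCovKernel:
    def test_zero_residuals_give_jitter_identity(self):
        Xi, _ = _bank()
        m = CovKernelModel(Xi=Xi, resid=np.zeros((40, 3)), L=np.eye(2), eta=1e-6)
        S = m.predict(np.array([[0.5, 0.5]]))
        assert np.allclose(S[0], 1e-6 * np.eye(3), atol=1e-15)

    def test_single_training_point_dominates_everywhere(self):
        Xi, resid = _bank(T=1)
        m = CovKernelModel(Xi=Xi, resid=resid, L=np.eye(2), eta=1e-6)
        C = np.outer(resid[0], resid[0])
        for q in ([0.0, 0.0], [5.0, -3.0]):
            S = m.predict(np.array([q]))[0]
            assert np.allclose(S, C + 1e-6 * np.eye(3), atol=1e-12)

    def test_weights_normalized_and_cov_symmetric_psd(self):
        Xi, resid = _bank(T=60, seed=2)
        m = CovKernelModel(Xi=Xi, resid=resid, L=2 * np.eye(2), eta=1e-6)
        Xq = np.random.default_rng(0).uniform(-1, 2, (25, 2))
        W = m.weights(Xq)
        assert np.allclose(W.sum(axis=1), 1.0, atol=1e-10)
        S = m.predict(Xq)
        assert np.allclose(S, np.swapaxes(S, 1, 2), atol=1e-12)
        assert min(np.linalg.eigvalsh(s).min() for s in S) >= -1e-10

    def test_tight_kernel_recovers_local_gram(self):
        Xi, resid = _bank(T=30, seed=3)
        m = CovKernelModel(Xi=Xi, resid=resid, L=400 * np.eye(2), eta=1e-6)
        i = 11
        S = m.predict(Xi[i][None, :])[0]
        C = np.outer(resid[i], resid[i])
        assert np.allclose(S, C + 1e-6 * np.eye(3), atol=1e-8)

    def test_default_eta(self, ring_gkr):
        assert ring_gkr.cov.eta == 1e-6

    def test_label_independent_covariance_recovered(self):
        # iid residuals with one true covariance: estimate within 10%
        rng = np.random.default_rng(5)
        T, N = 2000, 4
        A = rng.standard_normal((N, N)) * 0.5
        S0 = A @ A.T + 0.5 * np.eye(N)
        X = rng.uniform(0, 1, (T, 1))
        states = rng.multivariate_normal(np.zeros(N), S0, size=T) + 1.0
        ds = LabeledDataset(states, X, (LabelMeta("x"),))
        gp = fit_mean_gp(ds, seed=0)
        cov = fit_cov_kernel(ds, gp, seed=1, epochs=10)
        S_hat = cov.predict(np.array([[0.5]]))[0]
        assert np.linalg.norm(S_hat - S0) / np.linalg.norm(S0) < 0.10

    def test_trace_continuous_in_label(self, ring_gkr):
        x = 2.0
        t0 = np.trace(ring_gkr.predict_cov(np.array([[x]]))[0])
        deltas = [1e-2, 1e-3, 1e-4]
        gaps = [
            abs(np.trace(ring_gkr.predict_cov(np.array([[x + d]]))[0]) - t0)
            for d in deltas
        ]
        assert gaps[2] < gaps[0] + 1e-12
        assert gaps[2] < 1e-4 * max(t0, 1.0)


class TestLogLik:
    def test_matches_scipy_gaussian_density(self, ring_gkr, ring_data):
        sub = ring_data.subset(np.arange(20))
        ll = gkr_loglik(ring_gkr, sub)
        mu, S = ring_gkr.predict(sub.labels)
        ref = sum(
            multivariate_normal.logpdf(sub.states[i], mu[i], S[i])
            for i in range(20)
        )
        assert ll == pytest.approx(ref, rel=1e-10)

    def test_row_order_invariance(self, ring_gkr, ring_data):
        perm = np.random.default_rng(0).permutation(ring_data.n_points)
        assert gkr_loglik(ring_gkr, ring_data) == pytest.approx(
            gkr_loglik(ring_gkr, ring_data.subset(perm)), rel=1e-12
        )

    def test_true_labels_beat_shuffled_labels(self, ring_spec):
        ds = synthdata.sample_dataset(ring_spec, 200, seed=11)
        rng = np.random.default_rng(1)
        shuf = LabeledDataset(
            ds.states, ds.labels[rng.permutation(200)], ds.label_meta
        )
        m_true = fit_gkr(ds, seed=2)
        m_shuf = fit_gkr(shuf, seed=2)
        held = synthdata.sample_dataset(ring_spec, 200, seed=12)
        assert gkr_loglik(m_true, held) > gkr_loglik(m_shuf, held)


class TestGKRS:
    def test_silverman_bandwidth_formula(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(10_000)
        x = (x - x.mean()) / x.std()
        bw = silverman_bandwidths(x[:, None])[0]
        assert bw == pytest.approx((4 / 2) ** 0.2 * 10_000 ** (-0.2), rel=1e-12)
        assert bw == pytest.approx(0.18206, abs=5e-6)

    def test_bandwidth_scaling_properties(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((500, 2))
        b1 = silverman_bandwidths(x)
        assert np.allclose(silverman_bandwidths(2 * x), 2 * b1, rtol=1e-12)
        b_more = silverman_bandwidths(np.vstack([x, x + 0.01]))
        assert np.all(b_more < b1)

    def test_constant_label_rejected(self):
        with pytest.raises(ValueError):
            silverman_bandwidths(np.ones((50, 1)))

    def test_single_atom_moments(self):
        Xi = np.array([[0.0], [100.0]])
        resid = np.array([[1.0, -2.0], [5.0, 5.0]])

        class _Mean:
            def predict(self, X):
                return np.zeros((len(np.atleast_2d(X)), 2))

        from neurogeom.gkr import GKRSModel

        m = GKRSModel(mean=_Mean(), Xi=Xi, resid=resid, bandwidths=np.array([1.0]))
        mean, cov = gkrs_moments(m, np.array([0.0]))
        assert np.allclose(mean, resid[0])
        assert np.allclose(cov, np.outer(resid[0], resid[0]))

    def test_uniform_weights_match_direct_average(self):
        # all atoms at the query location -> uniform weights
        rng = np.random.default_rng(3)
        resid = rng.standard_normal((20, 3))

        class _Mean:
            def predict(self, X):
                return np.zeros((len(np.atleast_2d(X)), 3))

        from neurogeom.gkr import GKRSModel

        m = GKRSModel(
            mean=_Mean(),
            Xi=np.zeros((20, 1)),
            resid=resid,
            bandwidths=np.array([1.0]),
        )
        _, cov = gkrs_moments(m, np.array([0.0]))
        ref = np.einsum("ia,ib->ab", resid, resid) / 20
        assert np.allclose(cov, ref, atol=1e-12)

    def test_resampling_reproducible_and_consistent(self, ring_gkr, ring_data):
        gkrs = fit_gkrs(ring_data, ring_gkr.mean)
        xq = np.array([2.5])
        a = gkrs_resample(gkrs, xq, 500, seed=9)
        b = gkrs_resample(gkrs, xq, 500, seed=9)
        assert np.array_equal(a, b)
        mean, _ = gkrs_moments(gkrs, xq)
        big = gkrs_resample(gkrs, xq, 100_000, seed=1)
        se = big.std(axis=0) / np.sqrt(len(big))
        assert np.all(np.abs(big.mean(axis=0) - mean) < 4 * se + 1e-9)

    def test_total_noise_tracks_gkr(self, ring_gkr, ring_data):
        # the two covariance estimators agree on where noise is large
        gkrs = fit_gkrs(ring_data, ring_gkr.mean)
        Xq = np.linspace(0, 2 * np.pi, 30, endpoint=False)[:, None]
        tr_s = np.array([np.trace(gkrs_moments(gkrs, x)[1]) for x in Xq])
        tr_g = np.trace(ring_gkr.predict_cov(Xq), axis1=1, axis2=2)
        assert np.corrcoef(tr_s, tr_g)[0, 1] > 0


class TestDiagonalFlag:
    def test_diagonal_only_zeroes_off_diagonals(self, ring_gkr):
        diag = GKRModel(mean=ring_gkr.mean, cov=ring_gkr.cov, diagonal_only=True)
        S = diag.predict_cov(np.array([[1.0], [4.0]]))
        off = S - np.stack([np.diag(np.diag(s)) for s in S])
        assert np.all(off == 0)


class TestSerialization:
    def test_save_load_roundtrip_predictions(self, ring_gkr, tmp_path):
        path = tmp_path / "model.npz"
        ring_gkr.save(path)
        from neurogeom.gkr import GKRModel

        back = GKRModel.load(path)
        Xq = np.linspace(0, 6, 9)[:, None]
        assert np.allclose(back.predict_mean(Xq), ring_gkr.predict_mean(Xq))
        assert np.allclose(back.predict_cov(Xq), ring_gkr.predict_cov(Xq))
        assert back.diagonal_only == ring_gkr.diagonal_only
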