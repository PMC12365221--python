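import numpy as np
import pytest

from neurogeom.geometry import (
    fisher_information,
    lattice_area,
    make_ifgc,
    noise_traces,
    riemannian_metric,
    ssm_radius,
    tangent_frame,
    tangent_frames,
)
from neurogeom.synthdata import TwoNeuronSpec, two_neuron_fisher


@pytest.fixture
def linear_model(analytic_model_cls):
    W = np.array([[1.0, 0.0], [0.5, -1.0], [2.0, 3.0], [0.0, 1.0]])
    return analytic_model_cls(lambda x: W @ x[:2], lambda x: np.eye(4)), W


class TestTangentFrames:
    def test_linear_manifold_recovers_weight_columns(self, linear_model):
        model, W = linear_model
        fr = tangent_frame(model, np.array([0.3, -0.2]), dims=(0, 1), h=1e-3)
        assert np.allclose(fr.J, W, atol=1e-8)

    def test_richardson_halving_on_smooth_manifold(self, analytic_model_cls):
        model = analytic_model_cls(
            lambda x: np.array([np.sin(x[0]), np.cos(2 * x[0])]),
            lambda x: np.eye(2),
        )
        truth = np.array([np.cos(1.0), -2 * np.sin(2.0)])
        errs = []
        for h in (0.2, 0.1):
            fr = tangent_frame(model, np.array([1.0]), dims=(0,), h=h)
            errs.append(np.max(np.abs(fr.J[:, 0] - truth)))
        assert errs[1] < errs[0] / 3  # central differences: O(h^2)

    def test_one_sided_difference_at_boundary(self, linear_model):
        model, W = linear_model
        bounds = np.array([[0.0, 1.0], [0.0, 1.0]])
        fr = tangent_frame(
            model, np.array([0.0, 0.5]), dims=(0, 1), h=0.01, bounds=bounds
        )
        assert np.allclose(fr.J, W, atol=1e-8)  # exact for a linear map

    def test_batched_frames_match_single(self, ring_gkr):
        Xq = np.array([[1.0], [3.0], [5.0]])
        batch = tangent_frames(ring_gkr, Xq, dims=(0,), h=1e-3)
        for i, x in enumerate(Xq):
            single = tangent_frame(ring_gkr, x, dims=(0,), h=1e-3)
            assert np.allclose(batch[i], single.J, atol=1e-12)

    def test_invalid_step_rejected(self, linear_model):
        with pytest.raises(ValueError):
            tangent_frame(linear_model[0], np.zeros(2), dims=(0,), h=0.0)


class TestLatticeArea:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([1, 0, 0], [0, 1, 0], 1.0),  # orthonormal
            ([2, 0, 0], [4, 0, 0], 0.0),  # parallel
            ([1, 0], [1, 1], 1.0),  # 2-D cross product
        ],
    )
    def test_known_areas(self, a, b, expected):
        J = np.column_stack([a, b]).astype(float)
        assert lattice_area(J) == pytest.approx(expected, abs=1e-12)

    def test_requires_two_columns(self):
        with pytest.raises(ValueError):
            lattice_area(np.ones((3, 3)))

    def test_gram_identity_with_riemannian_metric(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            J = rng.standard_normal((6, 2))
            area = lattice_area(J)
            g = riemannian_metric(J)
            assert np.linalg.det(g) == pytest.approx(area**2, rel=1e-9)


class TestFisherAndNoise:
    def test_identity_case(self):
        I, tr = fisher_information(np.eye(4), np.eye(4))
        assert np.allclose(I, np.eye(4)) and tr == pytest.approx(4.0)

    def test_two_neuron_toy_trace(self):
        for rho in (0.0, -0.8, 0.5):
            spec = TwoNeuronSpec(rho=rho)
            dmu = (np.array(spec.mu2) - np.array(spec.mu1))[:, None]
            _, tr = fisher_information(dmu, spec.cov)
            assert tr == pytest.approx(two_neuron_fisher(spec), rel=1e-12)

    def test_matches_dprime_on_ring_fit(self, ring_gkr):
        # trace Fisher ~ d'^2 per unit label from the fitted moments
        x = 2.0
        h = 0.05
        mu_p = ring_gkr.predict_mean(np.array([[x + h]]))[0]
        mu_m = ring_gkr.predict_mean(np.array([[x - h]]))[0]
        S = ring_gkr.predict_cov(np.array([[x]]))[0]
        dmu = mu_p - mu_m
        d2 = float(dmu @ np.linalg.solve(S, dmu)) / (2 * h) ** 2
        J = tangent_frames(ring_gkr, np.array([[x]]), dims=(0,), h=h)[0]
        _, tr = fisher_information(J, S)
        assert tr == pytest.approx(d2, rel=0.05)

    def test_projected_noise_cases(self):
        U = np.column_stack([[1, 0, 0, 0], [0, 1, 0, 0]]).astype(float)
        total, proj = noise_traces(U, 2.0 * np.eye(4))
        assert total == pytest.approx(8.0) and proj == pytest.approx(4.0)
        # noise supported orthogonally to the tangent plane
        S = np.zeros((4, 4))
        S[2, 2] = S[3, 3] = 5.0
        total, proj = noise_traces(U, S)
        assert total == pytest.approx(10.0) and proj == pytest.approx(0.0)

    def test_total_noise_rotation_invariant(self):
        rng = np.random.default_rng(2)
        S = rng.standard_normal((5, 5))
        S = S @ S.T
        Q, _ = np.linalg.qr(rng.standard_normal((5, 5)))
        J = rng.standard_normal((5, 2))
        assert noise_traces(J, S)[0] == pytest.approx(
            noise_traces(Q @ J, Q @ S @ Q.T)[0], rel=1e-10
        )

    def test_orthonormal_variant_bounded_by_total(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            S = rng.standard_normal((6, 6))
            S = S @ S.T
            J = rng.standard_normal((6, 2))
            total, proj = noise_traces(J, S, orthonormal=True)
            assert proj <= total + 1e-10

    def test_metric_scale_quadratically(self):
        J = np.random.default_rng(4).standard_normal((5, 2))
        assert np.allclose(riemannian_metric(3 * J), 9 * riemannian_metric(J))


class TestSSMRadius:
    def test_constant_manifold_has_zero_radius(self, analytic_model_cls):
        model = analytic_model_cls(lambda x: np.ones(4), lambda x: np.eye(4))
        bounds = np.array([[0, 1], [0, 1], [0, 40]])
        assert ssm_radius(model, 10.0, bounds, n_points=200, seed=0) == 0.0

    def test_planar_circle_radius_recovered(self, analytic_model_cls):
        model = analytic_model_cls(
            lambda x: 2.0 * np.array([np.cos(np.pi * x[0]), np.sin(np.pi * x[0]), 0.0]),
            lambda x: np.eye(3),
        )
        bounds = np.array([[-1, 1], [-1, 1], [0, 40]])
        r = ssm_radius(model, 5.0, bounds, n_points=4000, seed=1)
        assert r == pytest.approx(2.0, rel=0.02)


class TestIFGC:
    def test_total_noise_preserved_exactly(self, ring_gkr):
        diag = make_ifgc(ring_gkr)
        Xq = np.linspace(0, 6, 12)[:, None]
        S = ring_gkr.predict_cov(Xq)
        D = diag.predict_cov(Xq)
        assert np.allclose(
            np.trace(S, axis1=1, axis2=2), np.trace(D, axis1=1, axis2=2), atol=1e-12
        )

    def test_two_neuron_fisher_rises_after_diagonalization(self, analytic_model_cls):
        spec = TwoNeuronSpec(rho=-0.8)
        model = analytic_model_cls(lambda x: np.zeros(2), lambda x: spec.cov)
        diag = make_ifgc(model)
        dmu = (np.array(spec.mu2) - np.array(spec.mu1))[:, None]
        x = np.zeros(2)
        _, tr = fisher_information(dmu, model.predict_cov(x[None])[0])
        _, tr_d = fisher_information(dmu, diag.predict_cov(x[None])[0])
        assert tr == pytest.approx(2 / 1.8, rel=1e-12)
        assert tr_d == pytest.approx(2.0, rel=1e-12)

    def test_already_diagonal_model_unchanged(self, analytic_model_cls):
        model = analytic_model_cls(lambda x: np.zeros(3), lambda x: np.diag([1.0, 2, 3]))
        diag = make_ifgc(model)
        X = np.zeros((2, 3))
        assert np.allclose(diag.predict_cov(X), model.predict_cov(X))
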