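"""Constrained minimization, the Hessian-block linear system, and the
chain rules into observables and Euclidean coordinates."""

import math
import warnings

import numpy as np
import pytest

from flexcon.engine import (
    ConvergenceError,
    IllConditionedWarning,
    Observable,
    PotentialModel,
    SaddlePointError,
    StaleGeometryError,
    constrained_jacobian,
    euclidean_constrained_derivatives,
    hessian_blocks,
    minimize_constrained,
    numeric_hessian,
    observable_total_derivative,
    quadratic_model,
)
from flexcon.geometry import geometric_jacobian
from flexcon.toy import fixture_molecule, synthetic_ff, tilted_double_well_model, toy2d_model


def _simple_quadratic():
    # V = (2u^2 + 2ud + 3d^2)/2: closed-form minimum d*(u) = -u/3
    K = np.array([[2.0, 1.0], [1.0, 3.0]])
    return quadratic_model(K, m=1)


class TestMinimize:
    def test_quadratic_closed_form_minimum(self):
        pt = minimize_constrained(_simple_quadratic(), np.array([1.0]), np.array([0.0]))
        np.testing.assert_allclose(pt.d_star, [-1.0 / 3.0], atol=1e-12)
        assert pt.grad_d_residual_norm <= 1e-10
        assert pt.min_eig_h_dd > 0

    def test_warm_start_selects_basin(self):
        model = tilted_double_well_model(barrier=1.0, tilt=0.3)
        right = minimize_constrained(model, np.array([0.0]), np.array([0.9]))
        left = minimize_constrained(model, np.array([0.0]), np.array([-0.9]))
        assert right.d_star[0] > 0.5 and left.d_star[0] < -0.5
        # grid oracle: dense scan of V confirms each is the basin minimum
        ys = np.linspace(-2, 2, 4001)
        vs = np.array([model.value([0.0], [y]) for y in ys])
        local_min_ys = ys[1:-1][(vs[1:-1] < vs[:-2]) & (vs[1:-1] < vs[2:])]
        assert min(abs(local_min_ys - right.d_star[0])) < 1e-3
        assert min(abs(local_min_ys - left.d_star[0])) < 1e-3

    def test_saddle_point_is_rejected(self):
        model = tilted_double_well_model(barrier=1.0, tilt=0.0)
        # d0 = 0 is the barrier top: a stationary point that is not a minimum
        with pytest.raises(SaddlePointError):
            minimize_constrained(model, np.array([0.0]), np.array([0.0]))

    def test_nonconvergence_raises_with_residual(self):
        model = _simple_quadratic()
        with pytest.raises(ConvergenceError, match="did not converge"):
            minimize_constrained(model, np.array([1.0]), np.array([50.0]), max_iter=0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            minimize_constrained(_simple_quadratic(), np.array([1.0, 2.0]), np.array([0.0]))


class TestConstrainedJacobian:
    def test_closed_form_one_dimensional(self):
        pt = minimize_constrained(_simple_quadratic(), np.array([2.0]), np.array([0.0]))
        np.testing.assert_allclose(pt.jacobian, [[-1.0 / 3.0]], atol=1e-12)

    def test_decoupled_gives_zero(self):
        K = np.diag([2.0, 5.0])
        pt = minimize_constrained(quadratic_model(K, m=1), np.array([1.3]), np.array([0.2]))
        np.testing.assert_allclose(pt.jacobian, [[0.0]], atol=1e-15)

    def test_quadratic_exactness_and_u_independence(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            m = int(rng.integers(1, 4))
            l = int(rng.integers(1, 5))
            A = rng.normal(size=(m + l, m + l))
            K = 0.5 * (A + A.T)
            K[m:, m:] = K[m:, m:] @ K[m:, m:].T + 0.1 * np.eye(l)
            model = quadratic_model(K, m)
            J_ref = -np.linalg.solve(K[m:, m:], K[m:, :m])
            for u in (rng.normal(size=m), rng.normal(size=m)):
                pt = minimize_constrained(model, u, rng.normal(size=l))
                np.testing.assert_allclose(pt.jacobian, J_ref, atol=1e-10)

    def test_richardson_fd_agrees_on_toy(self):
        from flexcon.finite_diff import richardson_fd
        from flexcon.toy import Toy2DParams, toy2d_minimizer

        model = toy2d_model()
        _, fprime = toy2d_minimizer()
        for x in np.linspace(-2, 2, 11):
            pt = minimize_constrained(model, np.array([x]), np.array([1.0]))
            fd = richardson_fd(model, np.array([x]), 0, 1e-3, base_point=pt)[0]
            assert abs(pt.jacobian[0, 0] - fd) <= 1e-6 * max(abs(fd), 1e-3)
            assert abs(pt.jacobian[0, 0] - fprime(x)) < 1e-10

    def test_ill_conditioning_warns(self):
        K = np.array([[1.0, 1.0, 0.0], [1.0, 1.0 + 1e-14, 0.0], [0.0, 0.0, 1.0]])
        # H_dd nearly singular
        model = quadratic_model(np.block([[np.eye(1), np.zeros((1, 3))], [np.zeros((3, 1)), K]]), m=1)
        u = np.array([0.0])
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                minimize_constrained(model, u, np.zeros(3))
            except SaddlePointError:
                pytest.skip("factorization failed outright on this platform")
            assert any(issubclass(w.category, IllConditionedWarning) for w in caught)


class TestHessianBlocks:
    def test_quadratic_blocks_exact(self):
        K = np.arange(16, dtype=float).reshape(4, 4)
        K = 0.5 * (K + K.T)
        model = quadratic_model(K + 8 * np.eye(4), m=2)
        H_dd, H_du = hessian_blocks(model, np.zeros(2), np.zeros(2))
        Kfull = K + 8 * np.eye(4)
        np.testing.assert_array_equal(H_dd, Kfull[2:, 2:])
        np.testing.assert_array_equal(H_du, Kfull[2:, :2])

    def test_numeric_fallback_matches_analytic(self):
        model = toy2d_model()
        fallback = numeric_hessian(model.gradient, m=1, l=1)
        u, d = np.array([0.7]), np.array([0.95])
        np.testing.assert_allclose(fallback(u, d), model.hessian(u, d), atol=1e-6)

    def test_model_consistency_probe(self):
        model = toy2d_model()
        model.check_consistency(np.array([0.5]), np.array([1.1]))
        broken = PotentialModel(
            m=1, l=1,
            value=model.value,
            gradient=lambda u, d: model.gradient(u, d) + np.array([0.5, 0.0]),
            hessian=model.hessian,
        )
        with pytest.raises(ValueError):
            broken.check_consistency(np.array([0.5]), np.array([1.1]))


class TestObservableChainRule:
    def test_u_only_observable_ignores_jacobian(self):
        obs = Observable(
            value=lambda u, d: float(u[0] ** 2),
            du=lambda u, d: np.array([2.0 * u[0]]),
            dd=lambda u, d: np.array([0.0]),
        )
        pt = minimize_constrained(_simple_quadratic(), np.array([1.5]), np.array([0.0]))
        np.testing.assert_allclose(observable_total_derivative(obs, pt), [3.0], atol=1e-14)

    def test_linear_observable_composition(self):
        c = 2.5
        obs = Observable(
            value=lambda u, d: c * float(d[0]),
            du=lambda u, d: np.array([0.0]),
            dd=lambda u, d: np.array([c]),
        )
        pt = minimize_constrained(_simple_quadratic(), np.array([1.0]), np.array([0.0]))
        np.testing.assert_allclose(observable_total_derivative(obs, pt), [c * (-1.0 / 3.0)], atol=1e-12)

    def test_hard_constraint_limit(self):
        # freezing d (J := 0) must reduce the total derivative to dO/du
        obs = Observable(
            value=lambda u, d: float(u[0] + 3 * d[0]),
            du=lambda u, d: np.array([1.0]),
            dd=lambda u, d: np.array([3.0]),
        )
        pt = minimize_constrained(_simple_quadratic(), np.array([1.0]), np.array([0.0]))
        pt.jacobian = np.zeros_like(pt.jacobian)
        np.testing.assert_allclose(observable_total_derivative(obs, pt), [1.0], atol=1e-15)


class TestEuclideanDerivatives:
    def test_atom1_rows_zero_and_j0_reduction(self, methanol):
        topo, internals, split, params = methanol
        model = synthetic_ff(topo, split, params)
        u = internals.to_vector(split.unconstrained_ids)
        d0 = internals.to_vector(split.constrained_ids)
        pt = minimize_constrained(model, u, d0)
        star = internals.copy()
        for nm, v in zip(split.constrained_ids, pt.d_star):
            star.set(nm, float(v))
        geo = geometric_jacobian(topo, star)
        table = euclidean_constrained_derivatives(topo, split, pt, geo)
        assert np.all(table[(1, "phi4")] == 0.0)
        pt.jacobian = np.zeros_like(pt.jacobian)
        bare = euclidean_constrained_derivatives(topo, split, pt, geo)
        for beta in topo.atoms():
            np.testing.assert_array_equal(bare[(beta, "phi4")], geo.get(beta, "phi4"))

    def test_stale_geometry_rejected(self, methanol):
        topo, internals, split, params = methanol
        model = synthetic_ff(topo, split, params)
        u = internals.to_vector(split.unconstrained_ids)
        d0 = internals.to_vector(split.constrained_ids)
        pt = minimize_constrained(model, u, d0)
        geo = geometric_jacobian(topo, internals)  # built at d0, not at d*
        with pytest.raises(StaleGeometryError):
            euclidean_constrained_derivatives(topo, split, pt, geo)

    def test_matches_richardson_fd_end_to_end(self, methanol):
        from flexcon.finite_diff import richardson_fd
        from flexcon.zmatrix import build_cartesian

        topo, internals, split, params = methanol
        model = synthetic_ff(topo, split, params)
        u = internals.to_vector(split.unconstrained_ids)
        d0 = internals.to_vector(split.constrained_ids)
        pt = minimize_constrained(model, u, d0)
        star = internals.copy()
        for nm, v in zip(split.constrained_ids, pt.d_star):
            star.set(nm, float(v))
        geo = geometric_jacobian(topo, star)
        table = euclidean_constrained_derivatives(topo, split, pt, geo)

        def positions(point):
            s = internals.copy()
            for nm, v in zip(split.unconstrained_ids, point.u):
                s.set(nm, float(v))
            for nm, v in zip(split.constrained_ids, point.d_star):
                s.set(nm, float(v))
            return build_cartesian(topo, s).xyz.ravel()

        fd = richardson_fd(model, u, 0, 1e-3, target=positions, base_point=pt)
        exact = np.stack([table[(b, "phi4")] for b in topo.atoms()]).ravel()
        scale = np.max(np.abs(fd))
        assert np.max(np.abs(exact - fd)) <= 1e-5 * scale


class TestFirstOrderPrediction:
    @pytest.mark.parametrize("which", ["toy", "methanol"])
    def test_halving_ratio_is_quadratic(self, which, methanol):
        if which == "toy":
            model = toy2d_model()
            u0 = np.array([0.8])
            d0 = np.array([1.0])
            w = np.array([1.0])
        else:
            topo, internals, split, params = methanol
            model = synthetic_ff(topo, split, params)
            u0 = np.array([1.0])
            d0 = internals.to_vector(split.constrained_ids)
            w = np.array([1.0])
        base = minimize_constrained(model, u0, d0)
        resid = []
        for j in range(5):
            eps = 0.1 / 2**j
            pt = minimize_constrained(model, u0 + eps * w, base.d_star)
            resid.append(np.linalg.norm(pt.d_star - base.d_star - eps * (base.jacobian @ w)))
        ratios = [resid[j] / resid[j + 1] for j in range(4)]
        assert all(3.5 <= r <= 4.5 for r in ratios), ratios

    def test_constraint_identity_second_order_residual(self):
        # the d-gradient at the first-order predicted point is O(eps^2)
        model = toy2d_model()
        base = minimize_constrained(model, np.array([0.6]), np.array([1.0]))
        norms = []
        for eps in (2e-2, 1e-2):
            d_pred = base.d_star + eps * base.jacobian @ np.array([1.0])
            g = model.gradient(base.u + eps, d_pred)[model.m:]
            norms.append(np.linalg.norm(g))
        assert norms[0] / norms[1] == pytest.approx(4.0, rel=0.25)
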