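"""Exact constrained-derivative engine.

Flexible constraints fix the constrained coordinates ``d`` to the values
``f(u)`` that minimize a potential ``V(u, d)`` at each value of the
unconstrained coordinates ``u``.  Differentiating the stationarity condition
``dV/dd = 0`` along ``u`` gives a linear system in the Hessian sub-blocks,

    H_dd J = -H_du,        J[I, i] = d f^I / d u^i,

whose solution is exact at the current point: no displaced minimizations and
no step-size parameter.  The total derivative of any observable ``O(u, d)``
restricted to the constrained subspace then follows by the chain rule,

    DO/Du_i = dO/du_i + sum_I dO/dd_I J[I, i],

and likewise for the body-fixed atomic positions via the geometric Jacobian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.linalg

from .geometry import GeometricJacobian
from .zmatrix import CoordinateSplit, InternalCoordinates, ZMatrixTopology

__all__ = [
    "PotentialModel",
    "Observable",
    "ConstrainedPoint",
    "ConvergenceError",
    "SaddlePointError",
    "IllConditionedWarning",
    "minimize_constrained",
    "constrained_jacobian",
    "hessian_blocks",
    "observable_total_derivative",
    "euclidean_constrained_derivatives",
    "numeric_hessian",
    "quadratic_model",
]


class ConvergenceError(RuntimeError):
    """Constrained minimization failed to reach the gradient tolerance."""


class SaddlePointError(RuntimeError):
    """The stationary point found is not a minimum (H_dd not positive definite)."""


class IllConditionedWarning(UserWarning):
    """H_dd condition estimate exceeds the configured threshold."""


@dataclass
class PotentialModel:
    """Energy model over internal coordinates, split into u (size M) and d
    (size L).

    ``value(u, d)`` returns a scalar; ``gradient`` a length M+L vector in
    (u, d) order; ``hessian`` a symmetric (M+L, M+L) matrix with the block
    layout [[H_uu, H_ud], [H_du, H_dd]].
    """

    m: int
    l: int
    value: Callable[[np.ndarray, np.ndarray], float]
    gradient: Callable[[np.ndarray, np.ndarray], np.ndarray]
    hessian: Callable[[np.ndarray, np.ndarray], np.ndarray]
    derivative_mode: str = "analytic"  # "analytic" | "numeric-fallback"
    name: str = "potential"

    @property
    def dim(self) -> int:
        return self.m + self.l

    def check_consistency(self, u, d, step: float = 1e-6, tol: float = 1e-4) -> None:
        """Spot-check gradient/Hessian against finite differences of value/
        gradient at one point (construction-time sanity probe)."""
        u = np.asarray(u, float)
        d = np.asarray(d, float)
        z = np.concatenate([u, d])
        g = self.gradient(u, d)
        H = self.hessian(u, d)
        if not np.allclose(H, H.T, rtol=1e-10, atol=1e-12):
            raise ValueError("hessian is not symmetric")
        for j in range(self.dim):
            e = np.zeros(self.dim)
            e[j] = step
            zp, zm = z + e, z - e
            fd_g = (self.value(zp[: self.m], zp[self.m :]) - self.value(zm[: self.m], zm[self.m :])) / (2 * step)
            if abs(fd_g - g[j]) > tol * max(1.0, abs(g[j])):
                raise ValueError(f"gradient component {j} inconsistent with value (fd {fd_g}, analytic {g[j]})")
            fd_h = (self.gradient(zp[: self.m], zp[self.m :]) - self.gradient(zm[: self.m], zm[self.m :])) / (2 * step)
            if np.max(np.abs(fd_h - H[:, j])) > tol * max(1.0, np.max(np.abs(H[:, j]))):
                raise ValueError(f"hessian column {j} inconsistent with gradient")


def numeric_hessian(model_gradient: Callable, m: int, l: int, step: float = 1e-5) -> Callable:
    """Central-difference Hessian built from an analytic gradient.

    Fallback for models without closed-form second derivatives; degrades the
    exactness guarantee to the accuracy of gradient differencing.
    """

    def hessian(u, d):
        z = np.concatenate([np.asarray(u, float), np.asarray(d, float)])
        dim = m + l
        H = np.empty((dim, dim))
        for j in range(dim):
            e = np.zeros(dim)
            e[j] = step
            zp, zm = z + e, z - e
            gp = model_gradient(zp[:m], zp[m:])
            gm = model_gradient(zm[:m], zm[m:])
            H[:, j] = (gp - gm) / (2 * step)
        if not np.all(np.isfinite(H)):
            raise FloatingPointError("non-finite entries in numeric-fallback Hessian")
        return 0.5 * (H + H.T)

    return hessian


@dataclass
class Observable:
    """Position-dependent observable with partials w.r.t. u and d."""

    value: Callable[[np.ndarray, np.ndarray], float]
    du: Callable[[np.ndarray, np.ndarray], np.ndarray]
    dd: Callable[[np.ndarray, np.ndarray], np.ndarray]
    name: str = "observable"


@dataclass
class ConstrainedPoint:
    """A point (u, f(u)) on the constrained subspace with its certificates."""

    u: np.ndarray
    d_star: np.ndarray
    energy: float
    grad_d_residual_norm: float
    h_dd: np.ndarray
    h_du: np.ndarray
    jacobian: np.ndarray  # (L, M)
    min_eig_h_dd: float
    iterations: int = 0
    condition_estimate: float = float("nan")


# ---------------------------------------------------------------------------
# minimization
# ---------------------------------------------------------------------------

def _solve_spd(H: np.ndarray, B: np.ndarray) -> np.ndarray:
    c, low = scipy.linalg.cho_factor(H, check_finite=False)
    return scipy.linalg.cho_solve((c, low), B, check_finite=False)


def minimize_constrained(
    model: PotentialModel,
    u: np.ndarray,
    d0: np.ndarray,
    *,
    gtol: float | None = None,
    max_iter: int = 500,
    cond_warn: float = 1e12,
) -> ConstrainedPoint:
    """Minimize V over d at fixed u (damped Newton, warm-started at d0) and
    assemble the exact constraint Jacobian.

    The analytic Hessian is required anyway by the linear system, so Newton
    costs nothing extra.  The converged point is certified to be a true
    minimum: H_dd must admit a Cholesky factorization, otherwise a
    :class:`SaddlePointError` is raised.  Basins are selected by the warm
    start; no global search is attempted.
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))
    d = np.atleast_1d(np.asarray(d0, dtype=float)).copy()
    if u.shape != (model.m,) or d.shape != (model.l,):
        raise ValueError(f"dimension mismatch: expected u({model.m},), d({model.l},)")
    if not np.all(np.isfinite(d)):
        raise ValueError("d0 must be finite")
    if gtol is None:
        gtol = 1e-10 if model.derivative_mode == "analytic" else 1e-8
    M = model.m

    iterations = 0
    residual = np.inf
    for iterations in range(max_iter + 1):
        g_d = model.gradient(u, d)[M:]
        residual = float(np.max(np.abs(g_d))) if model.l else 0.0
        if residual <= gtol:
            break
        H_dd = model.hessian(u, d)[M:, M:]
        lam = 0.0
        while True:
            try:
                step = -_solve_spd(H_dd + lam * np.eye(model.l), g_d)
                break
            except scipy.linalg.LinAlgError:
                lam = max(1e-8, 10.0 * lam) if lam else 1e-8 * max(1.0, float(np.max(np.abs(np.diag(H_dd)))))
        # backtracking on the energy; pure Newton steps are accepted near the minimum
        v0 = model.value(u, d)
        t = 1.0
        for _ in range(40):
            d_new = d + t * step
            if model.value(u, d_new) <= v0 + 1e-4 * t * float(g_d @ step):
                break
            t *= 0.5
        else:
            d_new = d + t * step
        d = d_new
    else:
        raise ConvergenceError(
            f"constrained minimization did not converge in {max_iter} iterations "
            f"(gradient infinity-norm {residual:.3e} > {gtol:.1e})"
        )

    H = model.hessian(u, d)
    H_dd = H[M:, M:]
    H_du = H[M:, :M]
    if model.l:
        try:
            scipy.linalg.cho_factor(H_dd, check_finite=False)
        except scipy.linalg.LinAlgError:
            eigs = np.linalg.eigvalsh(H_dd)
            raise SaddlePointError(
                f"stationary point is not a minimum: min eigenvalue of H_dd = {eigs[0]:.3e}"
            )
        min_eig = float(np.linalg.eigvalsh(H_dd)[0])
        cond = float(np.linalg.cond(H_dd))
    else:
        min_eig, cond = np.inf, 1.0

    point = ConstrainedPoint(
        u=u.copy(),
        d_star=d,
        energy=float(model.value(u, d)),
        grad_d_residual_norm=residual,
        h_dd=H_dd,
        h_du=H_du,
        jacobian=np.zeros((model.l, model.m)),
        min_eig_h_dd=min_eig,
        iterations=iterations,
        condition_estimate=cond,
    )
    point.jacobian = constrained_jacobian(point, cond_warn=cond_warn)
    return point


def constrained_jacobian(point: ConstrainedPoint, *, cond_warn: float = 1e12) -> np.ndarray:
    """Solve H_dd J = -H_du by symmetric positive-definite factorization."""
    L, M = point.h_du.shape
    if L == 0 or M == 0:
        return np.zeros((L, M))
    try:
        J = _solve_spd(point.h_dd, -point.h_du)
    except scipy.linalg.LinAlgError:
        raise SaddlePointError("H_dd is not positive definite; cannot form the constraint Jacobian")
    if np.isfinite(point.condition_estimate) and point.condition_estimate > cond_warn:
        warnings.warn(
            f"H_dd condition estimate {point.condition_estimate:.2e} exceeds {cond_warn:.0e}; "
            "the constraint Jacobian may lose accuracy",
            IllConditionedWarning,
            stacklevel=2,
        )
    resid = np.max(np.abs(point.h_dd @ J + point.h_du))
    scale = max(np.max(np.abs(point.h_du)), 1e-300)
    if resid > 1e-8 * scale:
        warnings.warn(
            f"linear-solve residual {resid:.2e} is large relative to |H_du| = {scale:.2e}",
            IllConditionedWarning,
            stacklevel=2,
        )
    return J


def hessian_blocks(model: PotentialModel, u: np.ndarray, d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(H_dd, H_du) sub-blocks in the coordinate-split ordering."""
    H = model.hessian(np.asarray(u, float), np.asarray(d, float))
    if not np.all(np.isfinite(H)):
        raise FloatingPointError("non-finite entries in Hessian evaluation")
    M = model.m
    return H[M:, M:], H[M:, :M]


# ---------------------------------------------------------------------------
# chain rules
# ---------------------------------------------------------------------------

def observable_total_derivative(observable: Observable, point: ConstrainedPoint) -> np.ndarray:
    """DO/Du_i = dO/du_i + sum_I dO/dd_I J[I,i] at (u, f(u))."""
    du = np.atleast_1d(np.asarray(observable.du(point.u, point.d_star), float))
    dd = np.atleast_1d(np.asarray(observable.dd(point.u, point.d_star), float))
    L, M = point.jacobian.shape
    if du.shape != (M,) or dd.shape != (L,):
        raise ValueError(f"observable partials have wrong shapes {du.shape}, {dd.shape}")
    return du + point.jacobian.T @ dd


class StaleGeometryError(RuntimeError):
    """Geometric Jacobian was evaluated at different internals than the point."""


def euclidean_constrained_derivatives(
    topology: ZMatrixTopology,
    split: CoordinateSplit,
    point: ConstrainedPoint,
    geo: GeometricJacobian,
    *,
    tol: float = 1e-10,
) -> dict[tuple[int, str], np.ndarray]:
    """Total derivatives Dx'_beta/Du_i of every atom's body-fixed position
    w.r.t. every unconstrained internal coordinate.

    ``geo`` must have been evaluated at the internals (u, f(u)) of ``point``.
    """
    expected = np.concatenate([point.u, point.d_star])
    actual = geo.internals.to_vector(list(split.unconstrained_ids) + list(split.constrained_ids))
    if np.max(np.abs(actual - expected)) > tol:
        raise StaleGeometryError(
            "geometric Jacobian evaluated at internals that differ from the constrained point"
        )
    out: dict[tuple[int, str], np.ndarray] = {}
    J = point.jacobian
    d_ids = split.constrained_ids
    for beta in topology.atoms():
        for i, u_name in enumerate(split.unconstrained_ids):
            vec = geo.get(beta, u_name).copy()
            for I, d_name in enumerate(d_ids):
                if J[I, i] != 0.0:
                    g = geo.get(beta, d_name)
                    if g is not None:
                        vec += g * J[I, i]
            out[(beta, u_name)] = vec
    return out


# ---------------------------------------------------------------------------
# convenience constructors
# ---------------------------------------------------------------------------

def quadratic_model(K: np.ndarray, m: int, lin: np.ndarray | None = None) -> PotentialModel:
    """Quadratic potential V(z) = z^T K z / 2 + lin . z over z = (u, d).

    For these models f is affine in u and the constraint Jacobian is the
    constant -K_dd^{-1} K_du, which makes them exact reference cases.
    """
    K = np.asarray(K, dtype=float)
    dim = K.shape[0]
    if K.shape != (dim, dim) or not np.allclose(K, K.T, atol=1e-12):
        raise ValueError("K must be square symmetric")
    l = dim - m
    c = np.zeros(dim) if lin is None else np.asarray(lin, dtype=float)

    def value(u, d):
        z = np.concatenate([np.atleast_1d(u), np.atleast_1d(d)])
        return float(0.5 * z @ K @ z + c @ z)

    def gradient(u, d):
        z = np.concatenate([np.atleast_1d(u), np.atleast_1d(d)])
        return K @ z + c

    def hessian(u, d):
        return K.copy()

    return PotentialModel(m=m, l=l, value=value, gradient=gradient, hessian=hessian, name="quadratic")
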