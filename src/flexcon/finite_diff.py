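"""Finite-difference comparator for constrained derivatives.

The straightforward alternative to the exact engine is to displace one
unconstrained coordinate, *re-minimize* the constrained ones at the
displaced point, and difference the results.  That estimate carries a
tunable step Δ with two failure modes: at small Δ the stiff constrained
coordinates barely move and their change drowns in the finite precision of
the stored values, while at large Δ the curvature of f — and, in rough
landscapes, changes in the very identity of the local minima — bias the
quotient.  This module reproduces that protocol (forward and central
schemes, warm-started re-minimizations, basin-hop detection, optional
fixed-decimal truncation emulating printed program output) together with the
normalized error metric used to compare the two methods across a set of
conformations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .engine import ConstrainedPoint, PotentialModel, minimize_constrained

__all__ = [
    "BasinHopWarning",
    "FDReport",
    "fd_derivative",
    "delta_sweep",
    "richardson_fd",
    "error_metric",
    "normalizer",
    "truncate_precision",
]


class BasinHopWarning(UserWarning):
    """The displaced minimization landed in a different basin than the base."""


def truncate_precision(values, decimals: int):
    """Round to a fixed number of decimal places (half-to-even), emulating
    the finite precision of printed coordinate output."""
    if decimals < 0:
        raise ValueError("decimals must be >= 0")
    arr = np.round(np.asarray(values, dtype=float), decimals)
    return float(arr) if arr.ndim == 0 else arr


def _minimize(model, u, d0, gtol, max_iter):
    return minimize_constrained(model, u, d0, gtol=gtol, max_iter=max_iter)


def fd_derivative(
    model: PotentialModel,
    u: np.ndarray,
    i: int,
    delta: float,
    *,
    scheme: str = "forward",
    target: Callable[[ConstrainedPoint], np.ndarray] | None = None,
    d0: np.ndarray | None = None,
    base_point: ConstrainedPoint | None = None,
    truncate_decimals: int | None = None,
    hop_threshold: float = 0.5,
    gtol: float | None = None,
    max_iter: int = 500,
) -> tuple[np.ndarray, dict]:
    """Finite-difference estimate of the derivative of a constrained-subspace
    quantity w.r.t. the i-th unconstrained coordinate.

    ``target(point)`` maps a converged constrained point to the quantity
    being differentiated (default: the minimizer d* itself).  Displaced
    minimizations are warm-started from the base d*.  Forward scheme:
    [g(u + Δ e_i) − g(u)]/Δ; central: [g(u + Δ/2 e_i) − g(u − Δ/2 e_i)]/Δ.
    ``truncate_decimals`` rounds the target values before differencing.
    Returns (estimate, metadata); metadata records endpoint convergence and
    whether any endpoint hopped basins (|Δd*| > hop_threshold per
    coordinate), which also emits a :class:`BasinHopWarning`.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if scheme not in ("forward", "central"):
        raise ValueError("scheme must be 'forward' or 'central'")
    u = np.atleast_1d(np.asarray(u, dtype=float))
    if not 0 <= i < model.m:
        raise IndexError(f"unconstrained index {i} out of range 0..{model.m - 1}")
    if target is None:
        target = lambda point: point.d_star

    if base_point is None:
        if d0 is None:
            raise ValueError("provide either base_point or a starting guess d0")
        base_point = _minimize(model, u, d0, gtol, max_iter)
    warm = base_point.d_star

    def evaluate(shift: float) -> tuple[np.ndarray, ConstrainedPoint]:
        if shift == 0.0:
            return np.atleast_1d(np.asarray(target(base_point), float)), base_point
        up = u.copy()
        up[i] += shift
        try:
            pt = _minimize(model, up, warm, gtol, max_iter)
        except Exception as exc:
            raise type(exc)(f"{exc} (endpoint u_{i} {shift:+g})") from exc
        return np.atleast_1d(np.asarray(target(pt), float)), pt

    if scheme == "forward":
        shifts = (delta, 0.0)
    else:
        shifts = (delta / 2.0, -delta / 2.0)
    (g_hi, pt_hi), (g_lo, pt_lo) = evaluate(shifts[0]), evaluate(shifts[1])
    hop = bool(
        np.any(np.abs(pt_hi.d_star - base_point.d_star) > hop_threshold)
        or np.any(np.abs(pt_lo.d_star - base_point.d_star) > hop_threshold)
    )
    if hop:
        warnings.warn(
            f"displaced minimization moved a constrained coordinate by more than "
            f"{hop_threshold} (possible basin change at delta={delta:g})",
            BasinHopWarning,
            stacklevel=2,
        )
    if truncate_decimals is not None:
        g_hi = truncate_precision(g_hi, truncate_decimals)
        g_lo = truncate_precision(g_lo, truncate_decimals)
    estimate = (g_hi - g_lo) / delta
    meta = {
        "scheme": scheme,
        "delta": delta,
        "basin_hop": hop,
        "iterations": (pt_hi.iterations, pt_lo.iterations),
        "residuals": (pt_hi.grad_d_residual_norm, pt_lo.grad_d_residual_norm),
    }
    return estimate, meta


def richardson_fd(
    model: PotentialModel,
    u: np.ndarray,
    i: int,
    delta: float,
    *,
    target=None,
    base_point=None,
    d0=None,
    **kwargs,
) -> np.ndarray:
    """Richardson-extrapolated central difference: (4 D(Δ/2) − D(Δ)) / 3.

    Cancels the leading O(Δ²) truncation error; test-oracle quality
    reference for the exact path.
    """
    e1, _ = fd_derivative(model, u, i, delta, scheme="central", target=target, base_point=base_point, d0=d0, **kwargs)
    e2, _ = fd_derivative(model, u, i, delta / 2.0, scheme="central", target=target, base_point=base_point, d0=d0, **kwargs)
    return (4.0 * e2 - e1) / 3.0


@dataclass
class FDReport:
    """Long-format record of a Δ sweep: one row per (target component, Δ)."""

    table: pd.DataFrame
    normalizers: dict[str, float] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path) -> None:
        self.table.to_json(path, orient="records", indent=1)

    def min_error_over_delta(self, target_name: str) -> float:
        sub = self.table[self.table["target"] == target_name]
        return float(sub["abs_error"].min())


def delta_sweep(
    model: PotentialModel,
    u: np.ndarray,
    deltas: Sequence[float],
    targets: dict[str, Callable[[ConstrainedPoint], float]],
    analytic: dict[str, float],
    *,
    scheme: str = "forward",
    i: int = 0,
    d0: np.ndarray | None = None,
    base_point: ConstrainedPoint | None = None,
    truncate_decimals: int | None = None,
    normalizers: dict[str, float] | None = None,
    **kwargs,
) -> FDReport:
    """Sweep Δ over scalar targets and tabulate FD vs analytic errors.

    ``targets`` maps names to scalar extractors of a constrained point;
    ``analytic`` supplies the exact derivative for each.  Rows are ordered by
    (target, Δ).  ``normalizers`` (default |analytic| per target) scale the
    normalized_error column.
    """
    deltas = list(deltas)
    if not deltas:
        raise ValueError("empty delta list")
    if len(set(deltas)) != len(deltas):
        raise ValueError("delta values must be unique")
    if base_point is None:
        if d0 is None:
            raise ValueError("provide either base_point or d0")
        base_point = minimize_constrained(model, np.atleast_1d(u), d0)
    rows = []
    for name in targets:
        extract = targets[name]
        ref = float(analytic[name])
        norm = float((normalizers or {}).get(name, abs(ref)))
        for delta in deltas:
            est, meta = fd_derivative(
                model,
                np.atleast_1d(u),
                i,
                delta,
                scheme=scheme,
                target=lambda p, ex=extract: np.array([ex(p)]),
                base_point=base_point,
                truncate_decimals=truncate_decimals,
                **kwargs,
            )
            err = abs(float(est[0]) - ref)
            rows.append(
                {
                    "target": name,
                    "delta": delta,
                    "scheme": scheme,
                    "fd_estimate": float(est[0]),
                    "analytic_value": ref,
                    "abs_error": err,
                    "normalized_error": err / norm if norm > 0 else np.nan,
                    "basin_hop": meta["basin_hop"],
                }
            )
    table = pd.DataFrame(rows, columns=[
        "target", "delta", "scheme", "fd_estimate", "analytic_value",
        "abs_error", "normalized_error", "basin_hop",
    ])
    return FDReport(table=table, normalizers={k: float((normalizers or {}).get(k, abs(float(analytic[k])))) for k in targets})


def normalizer(analytic_values: np.ndarray) -> np.ndarray:
    """Per-coordinate normalizing quantity N_mu: the maximum magnitude of the
    exact derivative over the conformation set.

    Single transcription point for the normalization convention; all error
    reporting delegates here.
    """
    analytic_values = np.asarray(analytic_values, dtype=float)
    return np.max(np.abs(analytic_values), axis=0)


def error_metric(
    fd_values: np.ndarray,
    analytic_values: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Normalized average absolute error per coordinate over conformations.

    ``fd_values`` and ``analytic_values`` are (n_conformations, n_coords)
    arrays of the two methods' derivatives.  Returns (per-coordinate errors,
    overall average).  E_mu = mean_s |FD − exact| / N_mu with N_mu from
    :func:`normalizer`; a zero normalizer is undefined and raises.
    """
    fd = np.atleast_2d(np.asarray(fd_values, dtype=float))
    na = np.atleast_2d(np.asarray(analytic_values, dtype=float))
    if fd.shape != na.shape:
        raise ValueError(f"shape mismatch {fd.shape} vs {na.shape}")
    if fd.shape[0] < 1:
        raise ValueError("need at least one conformation")
    n_mu = normalizer(na)
    if np.any(n_mu == 0):
        bad = np.nonzero(n_mu == 0)[0].tolist()
        raise ZeroDivisionError(f"zero normalizer for coordinate indices {bad}")
    per_coord = np.mean(np.abs(fd - na), axis=0) / n_mu
    return per_coord, float(np.mean(per_coord))
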