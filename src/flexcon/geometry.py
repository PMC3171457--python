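"""Analytic derivatives of body-fixed positions w.r.t. internal coordinates.

Changing one internal coordinate while holding the others fixed moves a
well-defined set of atoms rigidly: a bond-length change translates the whole
subtree beyond the bond along the bond direction; a bond-angle or dihedral
change rotates it about an axis through the positioning atom ``a(k)``.  The
first-order term of the Rodrigues rotation formula therefore gives every
angular derivative as a single cross product evaluated at the current
geometry — no finite differences anywhere.

Which atoms move is governed by the positioning chains plus the two
branching special cases (see :mod:`flexcon.zmatrix`): atoms referencing
atom 3 from atom 2 co-rotate with ``theta_3``, and a branch held by a phase
dihedral co-rotates with the principal dihedral it references.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .zmatrix import (
    COLLINEAR_TOL,
    DegenerateGeometryError,
    FrameConvention,
    DEFAULT_FRAME,
    InternalCoordinates,
    PrimedCoordinates,
    ZMatrixTopology,
    build_cartesian,
    chain_to_origin,
    fig4a_movers,
    fig4b_movers,
    parse_coordinate_name,
    _descendant_closure,
)

__all__ = [
    "rodrigues_rotate",
    "moves_under",
    "d_dbond",
    "angle_rotation_axis",
    "d_dangle",
    "d_ddihedral",
    "geometric_jacobian",
    "GeometricJacobian",
]


def rodrigues_rotate(v: np.ndarray, n: np.ndarray, angle: float) -> np.ndarray:
    """Rotate the free vector ``v`` about the unit axis ``n`` by ``angle``."""
    v = np.asarray(v, dtype=float)
    n = np.asarray(n, dtype=float)
    if abs(np.linalg.norm(n) - 1.0) > 1e-12:
        raise ValueError("rotation axis must be a unit vector")
    c, s = math.cos(angle), math.sin(angle)
    return v * c + np.cross(n, v) * s + n * np.dot(n, v) * (1.0 - c)


def _mover_set(topology: ZMatrixTopology, kind: str, k: int) -> set[int]:
    """Atoms whose body-fixed position changes when coordinate ``kind_k``
    changes (the sets of the bond/angle/dihedral mover rules)."""
    chain_movers = {
        beta
        for beta in topology.atoms()
        if k in chain_to_origin(topology, beta)
    }
    if kind == "b":
        return chain_movers
    if kind == "theta":
        if k == 3:
            # root-protocol atoms are terminal (enforced by validation), so
            # the co-rotating set is exactly the direct movers
            return chain_movers | fig4a_movers(topology)
        return chain_movers
    if kind == "phi":
        phase_children = {m for m, kk in fig4b_movers(topology).items() if kk == k}
        if phase_children:
            return chain_movers | _descendant_closure(topology, phase_children)
        return chain_movers
    raise KeyError(kind)


def moves_under(topology: ZMatrixTopology, beta: int, coordinate: str) -> bool:
    """Whether atom ``beta`` moves when the named internal coordinate changes."""
    kind, k = parse_coordinate_name(coordinate)
    if not (1 <= beta <= topology.atom_count):
        raise IndexError(f"atom index {beta} out of range")
    return beta in _mover_set(topology, kind, k)


def _bond_direction(topology, coords, k) -> np.ndarray:
    a = topology.bond_ref[k]
    v = coords.atom(k) - coords.atom(a)
    nv = np.linalg.norm(v)
    if nv < COLLINEAR_TOL:
        raise DegenerateGeometryError(f"coincident atoms {k} and {a}")
    return v / nv


def d_dbond(topology: ZMatrixTopology, coords: PrimedCoordinates, beta: int, k: int) -> np.ndarray:
    """d x'_beta / d b_k: the unit bond vector for movers, zero otherwise."""
    if not moves_under(topology, beta, f"b{k}"):
        return np.zeros(3)
    return _bond_direction(topology, coords, k)


def angle_rotation_axis(topology: ZMatrixTopology, coords: PrimedCoordinates, k: int) -> np.ndarray:
    """Unit normal of the (angle_ref, a(k), k) plane, oriented so that a
    positive rotation of atom k about it increases theta_k."""
    A = coords.atom(topology.bond_ref[k])
    u1 = coords.atom(topology.angle_ref[k]) - A
    v = coords.atom(k) - A
    n = np.cross(u1, v)
    nn = np.linalg.norm(n)
    if nn < COLLINEAR_TOL:
        raise DegenerateGeometryError(f"collinear reference triplet at atom {k}")
    return n / nn


def d_dangle(topology: ZMatrixTopology, coords: PrimedCoordinates, beta: int, k: int) -> np.ndarray:
    """d x'_beta / d theta_k = n_theta_k x (x'_beta - x'_a(k)) for movers."""
    if not moves_under(topology, beta, f"theta{k}"):
        return np.zeros(3)
    n = angle_rotation_axis(topology, coords, k)
    return np.cross(n, coords.atom(beta) - coords.atom(topology.bond_ref[k]))


def d_ddihedral(topology: ZMatrixTopology, coords: PrimedCoordinates, beta: int, k: int) -> np.ndarray:
    """d x'_beta / d phi_k = u x (x'_beta - x'_a(k)) for movers, where u is
    the unit vector from the angle reference to a(k) (the rotation axis)."""
    if not moves_under(topology, beta, f"phi{k}"):
        return np.zeros(3)
    A = coords.atom(topology.bond_ref[k])
    B = coords.atom(topology.angle_ref[k])
    u = A - B
    nu = np.linalg.norm(u)
    if nu < COLLINEAR_TOL:
        raise DegenerateGeometryError(f"coincident rotation-axis atoms for dihedral of atom {k}")
    return np.cross(u / nu, coords.atom(beta) - A)


@dataclass
class GeometricJacobian:
    """Sparse table (atom, coordinate) -> 3-vector d x'_atom / d coordinate.

    Entries outside the mover sets are structurally zero and never stored.
    ``internals`` records the evaluation point so downstream chain-rule
    consumers can detect stale geometry.
    """

    topology: ZMatrixTopology
    internals: InternalCoordinates
    entries: dict[tuple[int, str], np.ndarray]
    frame: FrameConvention = field(default=DEFAULT_FRAME)

    def get(self, beta: int, coordinate: str) -> np.ndarray:
        return self.entries.get((beta, coordinate), np.zeros(3))

    def dense(self, order: Iterable[str] | None = None) -> np.ndarray:
        """(N, 3, K) array over a coordinate ordering (default canonical)."""
        names = list(order) if order is not None else self.topology.coordinate_names()
        out = np.zeros((self.topology.atom_count, 3, len(names)))
        for (beta, name), vec in self.entries.items():
            try:
                j = names.index(name)
            except ValueError:
                continue
            out[beta - 1, :, j] = vec
        return out

    # -- export -----------------------------------------------------------
    def to_records(self) -> list[dict]:
        recs = [
            {"atom": beta, "coordinate": name, "dx": v[0], "dy": v[1], "dz": v[2]}
            for (beta, name), v in sorted(
                self.entries.items(), key=lambda kv: (kv[0][0], kv[0][1])
            )
        ]
        return recs

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.to_records(), columns=["atom", "coordinate", "dx", "dy", "dz"]).to_csv(
            path, index=False
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_records(), fh, indent=1)


def geometric_jacobian(
    topology: ZMatrixTopology,
    internals: InternalCoordinates,
    frame: FrameConvention = DEFAULT_FRAME,
) -> GeometricJacobian:
    """Assemble the full sparse geometric Jacobian at one geometry.

    One Cartesian build plus O(N^2) closed-form generator evaluations; the
    axes and bond directions are computed once per coordinate and applied to
    every mover.
    """
    coords = build_cartesian(topology, internals, frame)
    n = topology.atom_count
    entries: dict[tuple[int, str], np.ndarray] = {}
    for k in range(2, n + 1):
        name = f"b{k}"
        direction = _bond_direction(topology, coords, k)
        for beta in sorted(_mover_set(topology, "b", k)):
            entries[(beta, name)] = direction.copy()
    for k in range(3, n + 1):
        name = f"theta{k}"
        axis = angle_rotation_axis(topology, coords, k)
        pivot = coords.atom(topology.bond_ref[k])
        for beta in sorted(_mover_set(topology, "theta", k)):
            entries[(beta, name)] = np.cross(axis, coords.atom(beta) - pivot)
    for k in range(4, n + 1):
        name = f"phi{k}"
        A = coords.atom(topology.bond_ref[k])
        B = coords.atom(topology.angle_ref[k])
        u = A - B
        u = u / np.linalg.norm(u)
        for beta in sorted(_mover_set(topology, "phi", k)):
            entries[(beta, name)] = np.cross(u, coords.atom(beta) - A)
    return GeometricJacobian(topology, internals.copy(), entries, frame)
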