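"""Z-matrix topologies, internal coordinates and the body-fixed frame.

A molecule of ``N`` atoms is coordinated incrementally: atom ``k`` is placed
at a bond length ``b_k`` from a previously placed atom ``a(k)``, at a bond
angle ``theta_k`` measured at the vertex ``a(k)`` against an angle-reference
atom, and (for ``k >= 4``) at a dihedral ``phi_k`` against a third reference
atom.  The map ``a(.)`` forms a tree rooted at atom 1; following it from any
atom yields the positioning chain ``C(k) = [k, a(k), a(a(k)), ..., 1]``.

Positions are expressed in a body-fixed ("primed") frame that removes overall
translation and rotation: atom 1 sits at the origin, atom 2 on a designated
positive semi-axis, atom 3 in a designated coordinate plane with positive
in-plane component.  The frame is a package-wide convention read from one
place (:class:`FrameConvention`).

Reference atoms normally follow the chain (angle reference ``a(a(k))``,
dihedral reference ``a(a(a(k)))``).  Two deviations are legal, the branching
special cases of SASMIC-style coordination:

* atoms bonded to atom 2 take atom 3 as angle reference and atom 1 as
  dihedral reference (only possible protocol near the root);
* a branch-start atom is positioned by a *phase* dihedral whose reference is
  the atom declaring the *principal* dihedral on the same oriented bond.

All indices at this interface are 1-based, angles are radians; degrees appear
only at the file/CLI boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "FrameConvention",
    "ZMatrixTopology",
    "InternalCoordinates",
    "CoordinateSplit",
    "PrimedCoordinates",
    "SpecialCase",
    "validate_topology",
    "chain_to_origin",
    "detect_special_cases",
    "build_cartesian",
    "measure_internals",
    "wrap_angle",
]

COLLINEAR_TOL = 1e-10


class DegenerateGeometryError(ValueError):
    """Raised when reference atoms are coincident or collinear."""


def wrap_angle(phi):
    """Wrap an angle (radians) to the interval (-pi, pi]."""
    phi = np.asarray(phi, dtype=float)
    out = np.remainder(phi + np.pi, 2.0 * np.pi) - np.pi
    out = np.where(out == -np.pi, np.pi, out)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class FrameConvention:
    """Body-fixed frame gauge: which axes host atoms 2 and 3.

    ``axis2`` is the Cartesian axis index (0=x, 1=y, 2=z) of the positive
    semi-axis carrying atom 2; ``plane3`` is the axis index whose positive
    half-plane (together with ``axis2``) contains atom 3.  The default puts
    atom 2 on +z and atom 3 in the xz-plane with x > 0.  Only signed
    permutations of the canonical axes are allowed so that the gauge-zero
    components are exact zeros, not rounded ones.
    """

    axis2: int = 2
    plane3: int = 0

    def __post_init__(self):
        if self.axis2 == self.plane3 or not {self.axis2, self.plane3} <= {0, 1, 2}:
            raise ValueError("axis2 and plane3 must be distinct axis indices in {0,1,2}")

    @property
    def out_of_plane(self) -> int:
        return ({0, 1, 2} - {self.axis2, self.plane3}).pop()

    @classmethod
    def from_name(cls, name: str) -> "FrameConvention":
        presets = {"z-xz": cls(2, 0), "x-xy": cls(0, 1), "y-yz": cls(1, 2)}
        try:
            return presets[name]
        except KeyError:
            raise ValueError(f"unknown frame convention {name!r}; choose from {sorted(presets)}")


DEFAULT_FRAME = FrameConvention()

DIHEDRAL_KINDS = ("principal", "phase")


@dataclass(frozen=True)
class ZMatrixTopology:
    """Incremental coordination scheme of an ``N``-atom molecule.

    ``bond_ref[k]``, ``angle_ref[k]`` and ``dihedral_ref[k]`` are the 1-based
    reference atoms of atom ``k`` (dict keys are atom indices; entries exist
    for k>=2, k>=3, k>=4 respectively).  ``dihedral_kind[k]`` tags each
    dihedral as principal (rotation about the bond ``a(k)``–``angle_ref(k)``)
    or phase (branch placement relative to the principal atom).
    """

    atom_count: int
    element_labels: tuple[str, ...]
    bond_ref: dict[int, int]
    angle_ref: dict[int, int]
    dihedral_ref: dict[int, int]
    dihedral_kind: dict[int, str]

    def __post_init__(self):
        if self.atom_count < 1:
            raise ValueError("atom_count must be >= 1")
        if len(self.element_labels) != self.atom_count:
            raise ValueError("element_labels length must equal atom_count")

    @property
    def n_internals(self) -> int:
        n = self.atom_count
        return max(0, n - 1) + max(0, n - 2) + max(0, n - 3)

    def atoms(self) -> range:
        return range(1, self.atom_count + 1)

    def coordinate_names(self) -> list[str]:
        """Canonical ordering of the 3N-6 internal coordinates."""
        n = self.atom_count
        return (
            [f"b{k}" for k in range(2, n + 1)]
            + [f"theta{k}" for k in range(3, n + 1)]
            + [f"phi{k}" for k in range(4, n + 1)]
        )

    def coordinate_owner(self, name: str) -> int:
        """Atom index owning a coordinate name like ``'theta5'``."""
        kind, k = parse_coordinate_name(name)
        if k < {"b": 2, "theta": 3, "phi": 4}[kind] or k > self.atom_count:
            raise KeyError(f"coordinate {name!r} does not exist for N={self.atom_count}")
        return k


def parse_coordinate_name(name: str) -> tuple[str, int]:
    for kind in ("theta", "phi", "b"):
        if name.startswith(kind):
            try:
                return kind, int(name[len(kind):])
            except ValueError:
                break
    raise KeyError(f"malformed coordinate name {name!r}")


@dataclass
class InternalCoordinates:
    """Bond lengths, bond angles (radians) and dihedrals (radians).

    ``b[i]`` is the bond length of atom ``i+2``; ``theta[i]`` the bond angle
    of atom ``i+3``; ``phi[i]`` the dihedral of atom ``i+4``.
    """

    b: np.ndarray
    theta: np.ndarray
    phi: np.ndarray

    def __post_init__(self):
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        self.phi = np.atleast_1d(np.asarray(self.phi, dtype=float)) if np.size(self.phi) else np.zeros(0)

    @property
    def atom_count(self) -> int:
        return len(self.b) + 1

    def validate(self) -> None:
        n = self.atom_count
        if len(self.theta) != max(0, n - 2) or len(self.phi) != max(0, n - 3):
            raise ValueError("inconsistent internal-coordinate array lengths")
        if np.any(self.b <= 0):
            raise ValueError("bond lengths must be positive")
        if np.any(self.theta <= 0) or np.any(self.theta >= math.pi):
            raise ValueError("bond angles must lie strictly in (0, pi)")

    # -- named access ------------------------------------------------------
    def get(self, name: str) -> float:
        kind, k = parse_coordinate_name(name)
        return float({"b": self.b, "theta": self.theta, "phi": self.phi}[kind][k - {"b": 2, "theta": 3, "phi": 4}[kind]])

    def set(self, name: str, value: float) -> None:
        kind, k = parse_coordinate_name(name)
        {"b": self.b, "theta": self.theta, "phi": self.phi}[kind][k - {"b": 2, "theta": 3, "phi": 4}[kind]] = value

    def copy(self) -> "InternalCoordinates":
        return InternalCoordinates(self.b.copy(), self.theta.copy(), self.phi.copy())

    def to_vector(self, order: Sequence[str]) -> np.ndarray:
        return np.array([self.get(name) for name in order])

    def replace_from_vector(self, order: Sequence[str], values: np.ndarray) -> "InternalCoordinates":
        out = self.copy()
        for name, v in zip(order, values):
            out.set(name, float(v))
        return out

    def wrapped(self) -> "InternalCoordinates":
        out = self.copy()
        out.phi = wrap_angle(out.phi) if len(out.phi) else out.phi
        return out


@dataclass(frozen=True)
class CoordinateSplit:
    """Ordered partition of the internal coordinates into unconstrained (u)
    and constrained (d) sets."""

    unconstrained_ids: tuple[str, ...]
    constrained_ids: tuple[str, ...]

    @property
    def m(self) -> int:
        return len(self.unconstrained_ids)

    @property
    def l(self) -> int:
        return len(self.constrained_ids)

    def validate(self, topology: ZMatrixTopology) -> None:
        names = topology.coordinate_names()
        u, d = set(self.unconstrained_ids), set(self.constrained_ids)
        if u & d:
            raise ValueError(f"coordinates in both sets: {sorted(u & d)}")
        if u | d != set(names):
            missing = set(names) - (u | d)
            extra = (u | d) - set(names)
            raise ValueError(f"split does not cover internals (missing={sorted(missing)}, unknown={sorted(extra)})")

    @classmethod
    def from_unconstrained(cls, topology: ZMatrixTopology, unconstrained: Sequence[str]) -> "CoordinateSplit":
        uset = list(dict.fromkeys(unconstrained))
        names = topology.coordinate_names()
        for name in uset:
            if name not in names:
                raise ValueError(f"unknown unconstrained coordinate {name!r}")
        d = tuple(nm for nm in names if nm not in set(uset))
        split = cls(tuple(uset), d)
        split.validate(topology)
        return split


@dataclass
class PrimedCoordinates:
    """Per-atom positions in the body-fixed frame; row ``k-1`` is atom ``k``."""

    xyz: np.ndarray
    frame: FrameConvention = field(default=DEFAULT_FRAME)

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must be (N, 3)")

    def atom(self, k: int) -> np.ndarray:
        return self.xyz[k - 1]

    @property
    def atom_count(self) -> int:
        return self.xyz.shape[0]


# ---------------------------------------------------------------------------
# topology validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpecialCase:
    """A (mover atom, coordinate-owner atom) dependency outside the chain."""

    mover: int
    owner: int
    tag: str  # "fig4a_angle" | "fig4b_dihedral"


def _refs(topology: ZMatrixTopology, k: int) -> tuple[int | None, int | None, int | None]:
    return (
        topology.bond_ref.get(k),
        topology.angle_ref.get(k),
        topology.dihedral_ref.get(k),
    )


def principal_bond(topology: ZMatrixTopology, k: int) -> tuple[int, int]:
    """Oriented bond (a(k), angle_ref(k)) about which atom k's dihedral turns."""
    return (topology.bond_ref[k], topology.angle_ref[k])


def validate_topology(topology: ZMatrixTopology) -> list[str]:
    """Check every structural invariant; returns human-readable violations.

    Violations are data, not exceptions: an empty list means a valid topology.
    """
    t = topology
    n = t.atom_count
    out: list[str] = []

    for k in range(2, n + 1):
        if k not in t.bond_ref:
            out.append(f"missing bond reference at atom {k}")
    for k in range(3, n + 1):
        if k not in t.angle_ref:
            out.append(f"missing angle reference at atom {k}")
    for k in range(4, n + 1):
        if k not in t.dihedral_ref:
            out.append(f"missing dihedral reference at atom {k}")
        kind = t.dihedral_kind.get(k)
        if kind not in DIHEDRAL_KINDS:
            out.append(f"atom {k}: dihedral kind must be one of {DIHEDRAL_KINDS}, got {kind!r}")
    if out:
        return out  # reference maps incomplete; structural checks would KeyError

    # ordering + distinctness
    for k in range(2, n + 1):
        refs = [r for r in _refs(t, k) if r is not None]
        for r in refs:
            if not (1 <= r < k):
                out.append(f"forward reference at atom {k} (reference {r})")
        if len(set(refs)) != len(refs):
            out.append(f"repeated reference atoms at atom {k}: {refs}")
    if out:
        return out

    if n >= 2 and t.bond_ref[2] != 1:
        out.append("atom 2 must bond atom 1")
    for k in range(4, n + 1):
        if t.bond_ref[k] == 1:
            out.append(
                f"atom {k} bonds the root atom 1; the root is terminal and may only bond atoms 2 and 3"
            )
    # root-protocol atoms (bonded to atom 2, angle-ref 3) are terminal: an
    # atom coordinated from one would reference the off-axis atom 1 and its
    # motion under theta_3 would no longer be the rigid rotation the
    # closed-form derivative rules assume
    root_protocol = {
        k for k in range(4, n + 1) if t.bond_ref[k] == 2 and t.angle_ref.get(k) == 3
    }
    for k in range(4, n + 1):
        if t.bond_ref[k] in root_protocol:
            out.append(
                f"atom {k} is coordinated from atom {t.bond_ref[k]}, which uses the "
                "root reference protocol; such atoms are terminal"
            )
    if out:
        return out

    # one principal dihedral per oriented bond
    seen: dict[tuple[int, int], int] = {}
    for k in range(4, n + 1):
        if t.dihedral_kind[k] == "principal":
            bond = principal_bond(t, k)
            if bond in seen:
                out.append(
                    f"two principal dihedrals over bond {bond}: atoms {seen[bond]} and {k}"
                )
            else:
                seen[bond] = k

    # reference protocol: defaults or a recognized special-case pattern
    if n >= 3:
        a3, g3 = t.bond_ref[3], t.angle_ref[3]
        if a3 == 2 and g3 != 1:
            out.append("atom 3: angle reference must be atom 1 when bonded to atom 2")
        if a3 == 1 and g3 != 2:
            out.append("atom 3: angle reference must be atom 2 when bonded to atom 1")

    for k in range(4, n + 1):
        a, g, dref = t.bond_ref[k], t.angle_ref[k], t.dihedral_ref[k]
        kind = t.dihedral_kind[k]
        if a == 2:
            # near-root placement: only the root protocol is available
            if n < 3 or t.bond_ref[3] != 2:
                out.append(
                    f"atom {k} bonds atom 2 but atom 3 is not bonded to atom 2; "
                    "no valid angle-reference protocol exists"
                )
                continue
            if g != 3:
                out.append(f"atom {k}: atoms bonded to atom 2 must take atom 3 as angle reference")
                continue
            ok_phase = _is_phase_onto_principal(t, k)
            if dref != 1 and not ok_phase:
                out.append(
                    f"atom {k}: dihedral reference {dref} matches neither the root protocol "
                    "(atom 1) nor a phase reference to the principal atom of bond (2, 3)"
                )
        else:
            default_angle = t.bond_ref[a]
            if g != default_angle:
                out.append(
                    f"atom {k}: angle reference {g} deviates from the chain default {default_angle}"
                )
                continue
            default_dihedral = t.bond_ref.get(g) if g >= 2 else None
            if default_dihedral == a:  # can occur only in malformed trees
                default_dihedral = None
            if g == 1:
                # a(k) is atom 3 with a(3)=1: the only remaining reference is atom 2
                default_dihedral = 2
            if dref == default_dihedral:
                if kind != "principal":
                    out.append(
                        f"atom {k}: chain-default dihedral reference must be declared principal"
                    )
            elif _is_phase_onto_principal(t, k):
                pass
            else:
                out.append(
                    f"atom {k}: dihedral reference {dref} is neither the chain default "
                    f"({default_dihedral}) nor a phase reference to a principal atom on bond ({a}, {g})"
                )

    # declared-kind consistency for the root protocol
    for k in range(4, n + 1):
        if t.bond_ref[k] == 2 and t.angle_ref[k] == 3 and t.dihedral_ref[k] == 1:
            pass  # either kind is legal; duplicates caught by the principal-per-bond rule
    return out


def _is_phase_onto_principal(topology: ZMatrixTopology, k: int) -> bool:
    """True if atom k is a phase dihedral referencing the principal atom of
    its own oriented bond (the branch-phase pattern)."""
    t = topology
    m = t.dihedral_ref[k]
    return (
        t.dihedral_kind[k] == "phase"
        and m >= 4
        and m < k
        and t.bond_ref.get(m) == t.bond_ref[k]
        and t.angle_ref.get(m) == t.angle_ref[k]
        and t.dihedral_kind.get(m) == "principal"
    )


# ---------------------------------------------------------------------------
# chains and special cases
# ---------------------------------------------------------------------------

def chain_to_origin(topology: ZMatrixTopology, k: int) -> list[int]:
    """Positioning chain C(k) = [k, a(k), a²(k), ..., 1]."""
    if not (1 <= k <= topology.atom_count):
        raise IndexError(f"atom index {k} out of range 1..{topology.atom_count}")
    chain = [k]
    while chain[-1] != 1:
        chain.append(topology.bond_ref[chain[-1]])
    return chain


def _descendant_closure(topology: ZMatrixTopology, seeds: set[int]) -> set[int]:
    """Seeds plus every atom whose chain passes through a seed."""
    out = set(seeds)
    for beta in range(2, topology.atom_count + 1):
        k = beta
        while k != 1:
            if k in out:
                out.add(beta)
                break
            k = topology.bond_ref[k]
    return out


def fig4a_movers(topology: ZMatrixTopology) -> set[int]:
    """Atoms bonded to atom 2 that take atom 3 as angle reference (direct
    root-protocol movers of theta_3)."""
    return {
        k
        for k in range(4, topology.atom_count + 1)
        if topology.bond_ref[k] == 2 and topology.angle_ref[k] == 3
    }


def fig4b_movers(topology: ZMatrixTopology) -> dict[int, int]:
    """Map branch-start atom m -> principal atom k it phase-references."""
    return {
        m: topology.dihedral_ref[m]
        for m in range(4, topology.atom_count + 1)
        if _is_phase_onto_principal(topology, m)
    }


def detect_special_cases(topology: ZMatrixTopology) -> list[SpecialCase]:
    """All (mover, owner) pairs where an atom's position depends on internals
    of an atom outside its chain, ordered by (mover, owner)."""
    cases: list[SpecialCase] = []
    for beta in sorted(fig4a_movers(topology)):  # terminal atoms, no closure needed
        cases.append(SpecialCase(beta, 3, "fig4a_angle"))
    for m, k in fig4b_movers(topology).items():
        for beta in sorted(_descendant_closure(topology, {m})):
            if k not in chain_to_origin(topology, beta):
                cases.append(SpecialCase(beta, k, "fig4b_dihedral"))
    cases.sort(key=lambda c: (c.mover, c.owner))
    return cases


# ---------------------------------------------------------------------------
# build / measure
# ---------------------------------------------------------------------------

def _frame_vectors(frame: FrameConvention) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    e_axis = np.zeros(3)
    e_axis[frame.axis2] = 1.0
    e_plane = np.zeros(3)
    e_plane[frame.plane3] = 1.0
    return e_axis, e_plane, np.cross(e_axis, e_plane)


def _place(A, B, C, b, theta, phi, k):
    """Place an atom at bond length b from A, vertex angle theta against B,
    torsion phi against the plane (A, B, C)."""
    z_loc = A - B
    nz = np.linalg.norm(z_loc)
    if nz < COLLINEAR_TOL:
        raise DegenerateGeometryError(f"coincident reference atoms while placing atom {k}")
    z_loc = z_loc / nz
    w = C - B
    w_perp = w - np.dot(w, z_loc) * z_loc
    nw = np.linalg.norm(w_perp)
    if nw < COLLINEAR_TOL:
        raise DegenerateGeometryError(f"collinear reference triplet while placing atom {k}")
    x_loc = w_perp / nw
    y_loc = np.cross(z_loc, x_loc)
    d = -math.cos(theta) * z_loc + math.sin(theta) * (math.cos(phi) * x_loc + math.sin(phi) * y_loc)
    return A + b * d


def build_cartesian(
    topology: ZMatrixTopology,
    internals: InternalCoordinates,
    frame: FrameConvention = DEFAULT_FRAME,
) -> PrimedCoordinates:
    """Body-fixed Cartesian coordinates from internal coordinates.

    Gauge conditions hold exactly: atom 1 at the origin, atom 2 on the
    positive frame axis, atom 3 in the frame plane with positive in-plane
    component.
    """
    t = topology
    n = t.atom_count
    if internals.atom_count != n:
        raise ValueError("internals do not match topology size")
    internals.validate()
    e_axis, e_plane, _ = _frame_vectors(frame)
    xyz = np.zeros((n, 3))
    if n >= 2:
        xyz[1] = internals.get("b2") * e_axis
    if n >= 3:
        A = xyz[t.bond_ref[3] - 1]
        B = xyz[t.angle_ref[3] - 1]
        z_loc = A - B
        nz = np.linalg.norm(z_loc)
        if nz < COLLINEAR_TOL:
            raise DegenerateGeometryError("coincident reference atoms while placing atom 3")
        z_loc = z_loc / nz
        theta = internals.get("theta3")
        # in canonical components z_loc is +-e_axis, so the e_plane part is exact
        xyz[2] = A + internals.get("b3") * (-math.cos(theta) * z_loc + math.sin(theta) * e_plane)
    for k in range(4, n + 1):
        A = xyz[t.bond_ref[k] - 1]
        B = xyz[t.angle_ref[k] - 1]
        C = xyz[t.dihedral_ref[k] - 1]
        xyz[k - 1] = _place(
            A, B, C, internals.get(f"b{k}"), internals.get(f"theta{k}"), internals.get(f"phi{k}"), k
        )
    return PrimedCoordinates(xyz, frame)


def _vertex_angle(v1: np.ndarray, v2: np.ndarray, k: int) -> float:
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < COLLINEAR_TOL or n2 < COLLINEAR_TOL:
        raise DegenerateGeometryError(f"coincident atoms while measuring angle of atom {k}")
    c = np.dot(v1, v2) / (n1 * n2)
    return math.acos(min(1.0, max(-1.0, c)))


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed torsion of p1 about the p2–p3 axis relative to p4 (IUPAC sign,
    cis arrangement -> 0)."""
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < COLLINEAR_TOL or np.linalg.norm(n2) < COLLINEAR_TOL or nb2 < COLLINEAR_TOL:
        raise DegenerateGeometryError("collinear atoms in dihedral measurement")
    return math.atan2(np.dot(np.cross(n1, n2), b2 / nb2), np.dot(n1, n2))


def measure_internals(topology: ZMatrixTopology, coords: PrimedCoordinates) -> InternalCoordinates:
    """Inverse of :func:`build_cartesian` on its image (and on any rigidly
    displaced copy after re-gauging)."""
    t = topology
    n = t.atom_count
    xyz = coords.xyz
    b = np.empty(max(0, n - 1))
    theta = np.empty(max(0, n - 2))
    phi = np.empty(max(0, n - 3))
    for k in range(2, n + 1):
        v = xyz[k - 1] - xyz[t.bond_ref[k] - 1]
        d = np.linalg.norm(v)
        if d < COLLINEAR_TOL:
            raise DegenerateGeometryError(f"coincident bonded atoms {k} and {t.bond_ref[k]}")
        b[k - 2] = d
    for k in range(3, n + 1):
        A = xyz[t.bond_ref[k] - 1]
        theta[k - 3] = _vertex_angle(xyz[t.angle_ref[k] - 1] - A, xyz[k - 1] - A, k)
    for k in range(4, n + 1):
        phi[k - 4] = dihedral_angle(
            xyz[k - 1],
            xyz[t.bond_ref[k] - 1],
            xyz[t.angle_ref[k] - 1],
            xyz[t.dihedral_ref[k] - 1],
        )
    return InternalCoordinates(b, theta, phi)
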