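"""Self-contained study systems: a 2D toy potential with closed-form pieces,
a synthetic internal-coordinate force field, molecule fixtures, conformation
scans and a random-molecule generator.

The 2D toy system has one soft coordinate ``x`` and one stiff coordinate
``y`` oscillating in a deep harmonic well around ``y0``; a weak coupling term
shifts the well bottom as ``x`` moves, so the flexibly constrained value
``f(x)`` genuinely depends on ``x`` and is known in closed form — the ideal
end-to-end oracle.

The synthetic force field is defined *directly over internal coordinates*
(harmonic bonds/angles/stiff dihedrals plus cosine rotor terms), so value,
gradient and Hessian are closed-form and the engine's exactness claim can be
tested without any force-field package.  Cross-couplings make the
equilibrium value of each constrained coordinate a function of the
unconstrained dihedrals, q0(u) = q00 + c cos(u); with these couplings as the
only u-dependence the constrained minimizer is exactly q0(u) and the
constraint Jacobian has the closed form dq0/du = -c sin(u).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .engine import Observable, PotentialModel
from .zmatrix import (
    CoordinateSplit,
    InternalCoordinates,
    ZMatrixTopology,
    parse_coordinate_name,
    validate_topology,
    wrap_angle,
)

__all__ = [
    "Toy2DParams",
    "toy2d_model",
    "toy2d_minimizer",
    "toy2d_observable",
    "SyntheticFFParams",
    "HarmonicTerm",
    "TorsionTerm",
    "DoubleWellTerm",
    "synthetic_ff",
    "ff_equilibrium",
    "ff_equilibrium_jacobian",
    "fixture_molecule",
    "tilted_double_well_model",
    "scan_generator",
    "random_topology",
    "random_internals",
]

DEG = math.pi / 180.0


# ---------------------------------------------------------------------------
# 2D toy system
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Toy2DParams:
    """Coefficients of V(x, y) = a x^2/2 + k (y - y0)^2/2 + c x^2 y^2.

    ``k`` is the stiff harmonic constant of the constrained coordinate y,
    ``y0`` its uncoupled equilibrium, ``c`` the coupling that drags the well
    bottom as the unconstrained coordinate x moves, and ``a`` a soft
    restoring term in x.  Defaults are this package's synthetic stand-in
    parameter set; they keep H_yy = k + 2 c x^2 positive over the scanned
    range x in [x_min, x_max].
    """

    k: float = 100.0
    y0: float = 1.0
    c: float = 2.0
    a: float = 1.0
    x_min: float = -2.0
    x_max: float = 2.0

    def __post_init__(self):
        if self.k <= 0 or self.c < 0:
            raise ValueError("require k > 0 and c >= 0")
        if self.k + 2.0 * self.c * min(self.x_min**2, self.x_max**2) <= 0:
            raise ValueError("stiff-direction curvature must stay positive over the scan range")


def toy2d_model(params: Toy2DParams | None = None) -> PotentialModel:
    """PotentialModel (M=1 unconstrained x, L=1 constrained y) with analytic
    value, gradient and Hessian."""
    p = params or Toy2DParams()

    def value(u, d):
        x, y = float(np.atleast_1d(u)[0]), float(np.atleast_1d(d)[0])
        return 0.5 * p.a * x * x + 0.5 * p.k * (y - p.y0) ** 2 + p.c * x * x * y * y

    def gradient(u, d):
        x, y = float(np.atleast_1d(u)[0]), float(np.atleast_1d(d)[0])
        return np.array([p.a * x + 2.0 * p.c * x * y * y, p.k * (y - p.y0) + 2.0 * p.c * x * x * y])

    def hessian(u, d):
        x, y = float(np.atleast_1d(u)[0]), float(np.atleast_1d(d)[0])
        hxy = 4.0 * p.c * x * y
        return np.array(
            [[p.a + 2.0 * p.c * y * y, hxy], [hxy, p.k + 2.0 * p.c * x * x]]
        )

    return PotentialModel(m=1, l=1, value=value, gradient=gradient, hessian=hessian, name="toy2d")


def toy2d_minimizer(params: Toy2DParams | None = None):
    """Closed forms of the constrained minimizer f(x) = k y0 / (k + 2 c x^2)
    and its derivative; used as the independent oracle."""
    p = params or Toy2DParams()

    def f(x: float) -> float:
        return p.k * p.y0 / (p.k + 2.0 * p.c * x * x)

    def fprime(x: float) -> float:
        den = p.k + 2.0 * p.c * x * x
        return -4.0 * p.c * x * p.k * p.y0 / (den * den)

    return f, fprime


def toy2d_observable() -> Observable:
    """r = sqrt(x^2 + y^2), the distance of the particle to the origin."""

    def value(u, d):
        x, y = float(np.atleast_1d(u)[0]), float(np.atleast_1d(d)[0])
        return math.hypot(x, y)

    def du(u, d):
        x, y = float(np.atleast_1d(u)[0]), float(np.atleast_1d(d)[0])
        return np.array([x / math.hypot(x, y)])

    def dd(u, d):
        x, y = float(np.atleast_1d(u)[0]), float(np.atleast_1d(d)[0])
        return np.array([y / math.hypot(x, y)])

    return Observable(value=value, du=du, dd=dd, name="r")


def tilted_double_well_model(*, barrier: float = 1.0, tilt: float = 1.0) -> PotentialModel:
    """1+1D model with a double well in d, V = barrier (d^2-1)^2 + tilt u d.

    As u grows one well loses stability (fold at |tilt u| = 8 barrier
    /(3 sqrt 3)); used to exercise basin-hop detection in the
    finite-difference comparator.
    """

    def value(u, d):
        x, y = float(np.atleast_1d(u)[0]), float(np.atleast_1d(d)[0])
        return barrier * (y * y - 1.0) ** 2 + tilt * x * y

    def gradient(u, d):
        x, y = float(np.atleast_1d(u)[0]), float(np.atleast_1d(d)[0])
        return np.array([tilt * y, 4.0 * barrier * y * (y * y - 1.0) + tilt * x])

    def hessian(u, d):
        x, y = float(np.atleast_1d(u)[0]), float(np.atleast_1d(d)[0])
        return np.array([[0.0, tilt], [tilt, 4.0 * barrier * (3.0 * y * y - 1.0)]])

    return PotentialModel(m=1, l=1, value=value, gradient=gradient, hessian=hessian, name="tilted_double_well")


# ---------------------------------------------------------------------------
# synthetic force field over internal coordinates
# ---------------------------------------------------------------------------

@dataclass
class HarmonicTerm:
    """0.5 k (q - q0(u))^2 with q0(u) = q0 + sum_i couplings[u_i] cos(u_i)."""

    k: float
    q0: float
    couplings: dict[str, float] = field(default_factory=dict)
    wrap: bool = False  # wrap the displacement (dihedral coordinates)


@dataclass
class TorsionTerm:
    """Cosine rotor series sum_j v_j (1 + cos(n_j q - gamma_j))."""

    terms: list[tuple[float, int, float]] = field(default_factory=lambda: [(0.5, 3, 0.0)])


@dataclass
class DoubleWellTerm:
    """barrier ((q - q0)^2 - width^2)^2 / width^4 + tilt sin(u_partner) (q - q0).

    Engineered two-basin profile for one constrained coordinate: the tilt
    moves with one unconstrained dihedral so a finite displacement can push
    the warm-started minimization into the other well.
    """

    barrier: float
    width: float
    q0: float
    tilt: float
    partner: str


@dataclass
class SyntheticFFParams:
    """Closed-form force field over a topology's internal coordinates.

    ``harmonic`` maps constrained coordinate names to :class:`HarmonicTerm`;
    ``torsion`` maps unconstrained dihedral names to :class:`TorsionTerm`;
    ``cross`` holds optional bilinear couplings k_c (q_a - q_a0)(q_b - q_b0)
    between constrained coordinates; ``double_well`` optionally replaces one
    harmonic term.  All force constants must be positive and H_dd positive
    definite over the scan range (validated by sampling at construction).
    """

    harmonic: dict[str, HarmonicTerm]
    torsion: dict[str, TorsionTerm]
    cross: list[tuple[str, str, float]] = field(default_factory=list)
    double_well: DoubleWellTerm | None = None
    double_well_coord: str | None = None
    seed: int = 0

    def validate(self) -> None:
        for name, term in self.harmonic.items():
            if term.k <= 0:
                raise ValueError(f"force constant for {name} must be positive")
        if (self.double_well is None) != (self.double_well_coord is None):
            raise ValueError("double_well and double_well_coord must be set together")


def synthetic_ff(
    topology: ZMatrixTopology,
    split: CoordinateSplit,
    params: SyntheticFFParams,
    *,
    validate_spd: bool = True,
    spd_samples: int = 8,
) -> PotentialModel:
    """Build the analytic PotentialModel for a topology and split.

    With equilibrium-value couplings as the only u-dependence the minimizer
    is exactly d0(u) and J = d d0/d u; a bilinear ``cross`` block leaves the
    minimizer unchanged but makes H_dd non-diagonal.
    """
    params.validate()
    u_ids = list(split.unconstrained_ids)
    d_ids = list(split.constrained_ids)
    M, L = len(u_ids), len(d_ids)
    missing = [q for q in d_ids if q not in params.harmonic and q != params.double_well_coord]
    if missing:
        raise ValueError(f"no force-field term for constrained coordinates {missing}")
    u_index = {name: i for i, name in enumerate(u_ids)}

    K = np.array([params.harmonic[q].k if q in params.harmonic else 0.0 for q in d_ids])
    q00 = np.array([params.harmonic[q].q0 if q in params.harmonic else 0.0 for q in d_ids])
    # coupling matrix Cq[j, i]: q0_j(u) = q00_j + Cq[j, i] cos(u_i)
    Cq = np.zeros((L, M))
    wrap_mask = np.zeros(L, dtype=bool)
    for j, q in enumerate(d_ids):
        term = params.harmonic.get(q)
        if term is None:
            continue
        wrap_mask[j] = term.wrap
        for u_name, c in term.couplings.items():
            if u_name not in u_index:
                raise ValueError(f"coupling of {q} references unknown unconstrained coordinate {u_name}")
            Cq[j, u_index[u_name]] = c
    A = np.diag(K)
    for qa, qb, kc in params.cross:
        ja, jb = d_ids.index(qa), d_ids.index(qb)
        A[ja, jb] += kc
        A[jb, ja] += kc
    dw = params.double_well
    jdw = d_ids.index(params.double_well_coord) if dw is not None else -1
    idw = u_index[dw.partner] if dw is not None else -1

    def _d0(u):
        return q00 + Cq @ np.cos(u)

    def _resid(u, d):
        r = d - _d0(u)
        if wrap_mask.any():
            r = np.where(wrap_mask, wrap_angle(r), r)
        return r

    def _torsion_vgh(u):
        v = 0.0
        g = np.zeros(M)
        h = np.zeros(M)
        for name, term in params.torsion.items():
            i = u_index[name]
            ui = u[i]
            for vj, nj, gj in term.terms:
                v += vj * (1.0 + math.cos(nj * ui - gj))
                g[i] += -vj * nj * math.sin(nj * ui - gj)
                h[i] += -vj * nj * nj * math.cos(nj * ui - gj)
        return v, g, h

    def value(u, d):
        u = np.atleast_1d(np.asarray(u, float))
        d = np.atleast_1d(np.asarray(d, float))
        r = _resid(u, d)
        v, _, _ = _torsion_vgh(u)
        v += 0.5 * float(r @ A @ r)
        if dw is not None:
            s = d[jdw] - dw.q0
            v += dw.barrier * (s * s - dw.width**2) ** 2 / dw.width**4 + dw.tilt * math.sin(u[idw]) * s
        return v

    def gradient(u, d):
        u = np.atleast_1d(np.asarray(u, float))
        d = np.atleast_1d(np.asarray(d, float))
        r = _resid(u, d)
        Ar = A @ r
        _, gt, _ = _torsion_vgh(u)
        # d d0/d u_i = -Cq[:, i] sin(u_i)
        dd0 = -Cq * np.sin(u)[None, :]
        g_u = gt - dd0.T @ Ar
        g_d = Ar.copy()
        if dw is not None:
            s = d[jdw] - dw.q0
            g_d[jdw] += 4.0 * dw.barrier * s * (s * s - dw.width**2) / dw.width**4 + dw.tilt * math.sin(u[idw])
            g_u[idw] += dw.tilt * math.cos(u[idw]) * s
        return np.concatenate([g_u, g_d])

    def hessian(u, d):
        u = np.atleast_1d(np.asarray(u, float))
        d = np.atleast_1d(np.asarray(d, float))
        r = _resid(u, d)
        _, _, ht = _torsion_vgh(u)
        dd0 = -Cq * np.sin(u)[None, :]
        d2d0_diag = -Cq * np.cos(u)[None, :]  # d^2 d0_j / d u_i^2
        H_uu = dd0.T @ A @ dd0 + np.diag(ht) - np.diag(d2d0_diag.T @ (A @ r))
        H_du = -A @ dd0
        H_dd = A.copy()
        if dw is not None:
            s = d[jdw] - dw.q0
            H_dd[jdw, jdw] += 4.0 * dw.barrier * (3.0 * s * s - dw.width**2) / dw.width**4
            H_du[jdw, idw] += dw.tilt * math.cos(u[idw])
            H_uu[idw, idw] += -dw.tilt * math.sin(u[idw]) * s
        top = np.hstack([H_uu, H_du.T])
        bot = np.hstack([H_du, H_dd])
        return np.vstack([top, bot])

    model = PotentialModel(m=M, l=L, value=value, gradient=gradient, hessian=hessian, name="synthetic_ff")
    if validate_spd and L:
        rng = np.random.default_rng(params.seed)
        for _ in range(spd_samples):
            u = rng.uniform(-math.pi, math.pi, size=M)
            d = _d0(u)
            if dw is not None:
                d[jdw] = dw.q0 + dw.width
            H_dd = model.hessian(u, d)[M:, M:]
            if np.linalg.eigvalsh(H_dd)[0] <= 0:
                raise ValueError("H_dd is not positive definite over the sampled scan range")
    return model


def ff_equilibrium(params: SyntheticFFParams, split: CoordinateSplit, u: np.ndarray) -> np.ndarray:
    """Closed-form d0(u) of a coupling-only synthetic force field."""
    d_ids = list(split.constrained_ids)
    u_ids = list(split.unconstrained_ids)
    u = np.atleast_1d(np.asarray(u, float))
    out = np.empty(len(d_ids))
    for j, q in enumerate(d_ids):
        term = params.harmonic[q]
        out[j] = term.q0 + sum(c * math.cos(u[u_ids.index(nm)]) for nm, c in term.couplings.items())
    return out


def ff_equilibrium_jacobian(params: SyntheticFFParams, split: CoordinateSplit, u: np.ndarray) -> np.ndarray:
    """Closed-form d d0/d u, the reference Jacobian for coupling-only models."""
    d_ids = list(split.constrained_ids)
    u_ids = list(split.unconstrained_ids)
    u = np.atleast_1d(np.asarray(u, float))
    J = np.zeros((len(d_ids), len(u_ids)))
    for j, q in enumerate(d_ids):
        for nm, c in params.harmonic[q].couplings.items():
            i = u_ids.index(nm)
            J[j, i] = -c * math.sin(u[i])
    return J


# ---------------------------------------------------------------------------
# molecule fixtures
# ---------------------------------------------------------------------------

def _topology_from_rows(elements, rows) -> ZMatrixTopology:
    """rows: list of (bond_ref, angle_ref, dihedral_ref, kind) for atoms 2..N
    with None padding for undefined references."""
    bond_ref, angle_ref, dihedral_ref, kinds = {}, {}, {}, {}
    for k, (a, g, dref, kind) in enumerate(rows, start=2):
        bond_ref[k] = a
        if g is not None:
            angle_ref[k] = g
        if dref is not None:
            dihedral_ref[k] = dref
            kinds[k] = kind
    return ZMatrixTopology(
        atom_count=len(elements),
        element_labels=tuple(elements),
        bond_ref=bond_ref,
        angle_ref=angle_ref,
        dihedral_ref=dihedral_ref,
        dihedral_kind=kinds,
    )


def _internals_from_rows(values) -> InternalCoordinates:
    """values: per atom 2..N a tuple (b, theta_deg|None, phi_deg|None)."""
    b = [v[0] for v in values]
    theta = [v[1] * DEG for v in values if v[1] is not None]
    phi = [v[2] * DEG for v in values if v[2] is not None]
    return InternalCoordinates(np.array(b), np.array(theta), np.array(phi))


def _default_harmonics(topology, split, *, kb=300.0, ka=80.0, kd=30.0, internals=None):
    """Harmonic terms for every constrained coordinate, centred on the
    fixture's reference internals."""
    terms = {}
    for q in split.constrained_ids:
        kind, _ = parse_coordinate_name(q)
        q0 = internals.get(q) if internals is not None else {"b": 1.2, "theta": 109.5 * DEG, "phi": math.pi}[kind]
        if kind == "b":
            terms[q] = HarmonicTerm(k=kb, q0=q0)
        elif kind == "theta":
            terms[q] = HarmonicTerm(k=ka, q0=q0)
        else:
            terms[q] = HarmonicTerm(k=kd, q0=q0, wrap=True)
    return terms


def fixture_molecule(name: str):
    """Bundled molecule fixtures: ``methanol_like`` (6 atoms, 1 unconstrained
    dihedral), ``nma_like`` (12 atoms, 3), ``gly3_like`` (30 atoms, 7).

    Returns (topology, internals, split, ff_params).  The topologies are
    idealized emulations of a small alcohol, a capped amide and a
    tri-peptide: atom counts, branching patterns (including both special
    reference cases) and the unconstrained rotor sets mirror those systems,
    but geometries and energies are synthetic.
    """
    if name == "methanol_like":
        topology = _topology_from_rows(
            ["H", "C", "O", "H", "H", "H"],
            [
                (1, None, None, None),
                (2, 1, None, None),
                (2, 3, 1, "principal"),
                (2, 3, 4, "phase"),
                (2, 3, 4, "phase"),
            ],
        )
        internals = _internals_from_rows(
            [
                (1.09, None, None),
                (1.41, 109.5, None),
                (1.09, 109.5, 60.0),
                (1.09, 109.5, 120.0),
                (1.09, 109.5, -120.0),
            ]
        )
        split = CoordinateSplit.from_unconstrained(topology, ["phi4"])
        harmonic = _default_harmonics(topology, split, internals=internals)
        # atom 5's bond, angle and phase dihedral follow
        # the rotor; the bond is stiff so its motion is tiny
        harmonic["b5"].couplings = {"phi4": 0.01}
        harmonic["theta5"].couplings = {"phi4": 0.03}
        harmonic["phi5"].couplings = {"phi4": 0.05}
        harmonic["theta6"].couplings = {"phi4": -0.02}
        params = SyntheticFFParams(
            harmonic=harmonic,
            torsion={"phi4": TorsionTerm([(0.5, 3, 0.0)])},
            cross=[("theta5", "phi5", 4.0)],
        )
    elif name == "nma_like":
        topology = _topology_from_rows(
            ["H", "C", "C", "O", "N", "H", "C", "H", "H", "H", "H", "H"],
            [
                (1, None, None, None),       # 2 C (methyl)
                (2, 1, None, None),          # 3 C (carbonyl)
                (3, 2, 1, "principal"),      # 4 O   : methyl-amide rotor (bond 3-2)
                (3, 2, 4, "phase"),          # 5 N   : branch at carbonyl -> fig4b
                (5, 3, 2, "principal"),      # 6 H(N): amide rotation (bond 5-3)
                (5, 3, 6, "phase"),          # 7 C (methyl2) -> fig4b
                (7, 5, 3, "principal"),      # 8 H   : methyl2 rotor (bond 7-5)
                (7, 5, 8, "phase"),          # 9 H
                (7, 5, 8, "phase"),          # 10 H
                (2, 3, 1, "phase"),          # 11 H  : fig4a (root protocol)
                (2, 3, 1, "phase"),          # 12 H  : fig4a
            ],
        )
        internals = _internals_from_rows(
            [
                (1.09, None, None),
                (1.52, 109.5, None),
                (1.23, 121.0, 30.0),
                (1.34, 115.0, 180.0),
                (1.01, 119.0, 0.0),
                (1.45, 121.0, 180.0),
                (1.09, 109.5, 60.0),
                (1.09, 109.5, 120.0),
                (1.09, 109.5, -120.0),
                (1.09, 109.5, 120.0),
                (1.09, 109.5, -120.0),
            ]
        )
        split = CoordinateSplit.from_unconstrained(topology, ["phi4", "phi6", "phi8"])
        harmonic = _default_harmonics(topology, split, internals=internals)
        harmonic["b5"].couplings = {"phi4": 0.008}
        harmonic["theta5"].couplings = {"phi4": 0.04, "phi6": 0.02}
        harmonic["phi5"].couplings = {"phi4": 0.05}
        harmonic["theta7"].couplings = {"phi6": 0.03}
        harmonic["phi7"].couplings = {"phi6": -0.04}
        harmonic["theta9"].couplings = {"phi8": 0.03}
        harmonic["phi9"].couplings = {"phi8": 0.05}
        harmonic["theta11"].couplings = {"phi4": -0.02}
        params = SyntheticFFParams(
            harmonic=harmonic,
            torsion={
                "phi4": TorsionTerm([(0.4, 3, 0.0)]),
                "phi6": TorsionTerm([(1.0, 2, 0.0)]),
                "phi8": TorsionTerm([(0.4, 3, 0.0)]),
            },
            cross=[("theta5", "phi5", 3.0), ("b5", "theta5", 2.0)],
        )
    elif name == "gly3_like":
        elements = [
            "H", "C", "C", "O", "H", "H",            # acetyl cap: H, CH3 carbon, C', O + 2 methyl H
            "N", "H", "C", "C", "H", "H", "O",        # residue 1: N, H(N), CA, C', 2 H(CA), O
            "N", "H", "C", "C", "H", "H", "O",        # residue 2
            "N", "H", "C", "C", "H", "H", "O",        # residue 3
            "N", "H", "H",                            # C-terminal amide NH2
        ]
        rows = [
            (1, None, None, None),        # 2 C methyl
            (2, 1, None, None),           # 3 C carbonyl (cap)
            (3, 2, 1, "principal"),       # 4 O    : rotor about bond 3-2 (unconstrained)
            (2, 3, 1, "phase"),           # 5 H    : fig4a
            (2, 3, 1, "phase"),           # 6 H    : fig4a
            (3, 2, 4, "phase"),           # 7 N1   : fig4b at cap carbonyl
            (7, 3, 2, "principal"),       # 8 H(N1): omega1 (bond 7-3, peptide) constrained
            (7, 3, 8, "phase"),           # 9 CA1  : fig4b
            (9, 7, 3, "principal"),       # 10 C'1 : phi1 (bond 9-7) unconstrained
            (9, 7, 10, "phase"),          # 11 H(CA1)
            (9, 7, 10, "phase"),          # 12 H(CA1)
            (10, 9, 7, "principal"),      # 13 O1  : psi1 (bond 10-9) unconstrained
            (10, 9, 13, "phase"),         # 14 N2
            (14, 10, 9, "principal"),     # 15 H(N2): omega2 constrained
            (14, 10, 15, "phase"),        # 16 CA2
            (16, 14, 10, "principal"),    # 17 C'2 : phi2 unconstrained
            (16, 14, 17, "phase"),        # 18 H(CA2)
            (16, 14, 17, "phase"),        # 19 H(CA2)
            (17, 16, 14, "principal"),    # 20 O2  : psi2 unconstrained
            (17, 16, 20, "phase"),        # 21 N3
            (21, 17, 16, "principal"),    # 22 H(N3): omega3 constrained
            (21, 17, 22, "phase"),        # 23 CA3
            (23, 21, 17, "principal"),    # 24 C'3 : phi3 unconstrained
            (23, 21, 24, "phase"),        # 25 H(CA3)
            (23, 21, 24, "phase"),        # 26 H(CA3)
            (24, 23, 21, "principal"),    # 27 O3  : psi3 unconstrained
            (24, 23, 27, "phase"),        # 28 N4 (amide)
            (28, 24, 23, "principal"),    # 29 H(N4): amide rotation constrained
            (28, 24, 29, "phase"),        # 30 H(N4)
        ]
        geom = [
            (1.09, None, None),
            (1.52, 109.5, None),
            (1.23, 121.0, 40.0),
            (1.09, 109.5, 120.0),
            (1.09, 109.5, -120.0),
            (1.34, 115.0, 180.0),
            (1.01, 119.0, 0.0),
            (1.45, 121.0, 180.0),
            (1.52, 110.0, -80.0),
            (1.09, 109.5, 120.0),
            (1.09, 109.5, -120.0),
            (1.23, 121.0, -30.0),
            (1.34, 115.0, 180.0),
            (1.01, 119.0, 0.0),
            (1.45, 121.0, 180.0),
            (1.52, 110.0, -80.0),
            (1.09, 109.5, 120.0),
            (1.09, 109.5, -120.0),
            (1.23, 121.0, -30.0),
            (1.34, 115.0, 180.0),
            (1.01, 119.0, 0.0),
            (1.45, 121.0, 180.0),
            (1.52, 110.0, -80.0),
            (1.09, 109.5, 120.0),
            (1.09, 109.5, -120.0),
            (1.23, 121.0, -30.0),
            (1.34, 115.0, 180.0),
            (1.01, 119.0, 0.0),
            (1.45, 121.0, 180.0),
        ]
        topology = _topology_from_rows(elements, rows)
        internals = _internals_from_rows(geom)
        split = CoordinateSplit.from_unconstrained(
            topology, ["phi4", "phi10", "phi13", "phi17", "phi20", "phi24", "phi27"]
        )
        harmonic = _default_harmonics(topology, split, internals=internals)
        harmonic["phi8"].couplings = {"phi10": 0.06}
        harmonic["theta7"].couplings = {"phi4": 0.03}
        harmonic["phi14"].couplings = {"phi13": 0.05, "phi17": -0.03}
        harmonic["theta14"].couplings = {"phi13": 0.04}
        harmonic["phi15"].couplings = {"phi17": 0.05}
        harmonic["theta21"].couplings = {"phi20": 0.04}
        harmonic["phi22"].couplings = {"phi24": 0.05}
        harmonic["phi28"].couplings = {"phi27": 0.06}
        harmonic["b14"].couplings = {"phi13": 0.006}
        params = SyntheticFFParams(
            harmonic=harmonic,
            torsion={
                "phi4": TorsionTerm([(0.4, 3, 0.0)]),
                "phi10": TorsionTerm([(0.8, 2, 0.0), (0.3, 3, 0.5)]),
                "phi13": TorsionTerm([(0.8, 2, 0.0), (0.3, 3, 0.5)]),
                "phi17": TorsionTerm([(0.8, 2, 0.0), (0.3, 3, 0.5)]),
                "phi20": TorsionTerm([(0.8, 2, 0.0), (0.3, 3, 0.5)]),
                "phi24": TorsionTerm([(0.8, 2, 0.0), (0.3, 3, 0.5)]),
                "phi27": TorsionTerm([(0.8, 2, 0.0), (0.3, 3, 0.5)]),
            },
            cross=[("theta9", "phi9", 3.0)],
        )
    else:
        raise KeyError(f"unknown fixture {name!r}; choose methanol_like, nma_like or gly3_like")

    errors = validate_topology(topology)
    if errors:  # defensive: fixtures are constructed to be valid
        raise AssertionError(f"fixture {name} failed validation: {errors}")
    return topology, internals, split, params


# ---------------------------------------------------------------------------
# conformation scans
# ---------------------------------------------------------------------------

def scan_generator(
    split: CoordinateSplit,
    *,
    grid: dict[str, tuple[float, float, float]] | None = None,
    n_samples: int | None = None,
    seed: int | None = None,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> np.ndarray:
    """Deterministic conformation sets over the unconstrained coordinates.

    Grid mode: per-coordinate (start, stop, step) in radians, stop inclusive
    up to floating slack, enumerated lexicographically.  Random mode: seeded
    uniform samples over per-coordinate ranges (default (-pi, pi]).
    Returns an (n_conformations, M) array.
    """
    u_ids = list(split.unconstrained_ids)
    if grid is not None:
        axes = []
        for name in u_ids:
            if name not in grid:
                raise ValueError(f"grid specification missing coordinate {name}")
            start, stop, step = grid[name]
            if step <= 0:
                raise ValueError(f"non-positive step for {name}")
            count = int(math.floor((stop - start) / step + 1e-9)) + 1
            if count < 1:
                raise ValueError(f"empty grid for {name}")
            axes.append(start + step * np.arange(count))
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=-1)
    if n_samples is None or seed is None:
        raise ValueError("provide either grid= or both n_samples= and seed=")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    lo = np.array([(ranges or {}).get(nm, (-math.pi, math.pi))[0] for nm in u_ids])
    hi = np.array([(ranges or {}).get(nm, (-math.pi, math.pi))[1] for nm in u_ids])
    return rng.uniform(lo, hi, size=(n_samples, len(u_ids)))


# ---------------------------------------------------------------------------
# random molecules (synthetic test-condition generator)
# ---------------------------------------------------------------------------

def random_topology(rng: np.random.Generator, n_atoms: int, *, p_fig4a: float = 0.3) -> ZMatrixTopology:
    """Random valid SASMIC-style topology with occasional branching and
    root-protocol atoms; used to sweep the geometric-derivative oracle."""
    if n_atoms < 2:
        raise ValueError("need at least two atoms")
    rows: list[tuple] = [(1, None, None, None)]
    if n_atoms >= 3:
        rows.append((2, 1, None, None))
    principal_on: dict[tuple[int, int], int] = {}
    root_protocol: set[int] = set()
    for k in range(4, n_atoms + 1):
        # root-protocol atoms are terminal, so never pick one as parent
        candidates = [a for a in range(2, k) if a not in root_protocol]
        if rng.random() < p_fig4a:
            a = 2
        else:
            a = int(rng.choice(candidates))
        if a == 2:
            root_protocol.add(k)
            g = 3
            bond = (2, 3)
            if bond in principal_on and rng.random() < 0.5:
                dref, kind = principal_on[bond], "phase"
            elif bond not in principal_on and rng.random() < 0.5:
                dref, kind = 1, "principal"
                principal_on[bond] = k
            else:
                dref, kind = 1, "phase"
        else:
            g = rows[a - 2][0]  # a(a)
            bond = (a, g)
            if bond in principal_on:
                dref, kind = principal_on[bond], "phase"
            else:
                dref = rows[g - 2][0] if g >= 2 else 2
                kind = "principal"
                principal_on[bond] = k
        rows.append((a, g, dref, kind))
    elements = ["C"] * n_atoms
    topo = _topology_from_rows(elements, rows)
    errors = validate_topology(topo)
    if errors:
        raise AssertionError(f"random topology invalid: {errors}")
    return topo


def random_internals(rng: np.random.Generator, n_atoms: int) -> InternalCoordinates:
    """Random well-conditioned internal coordinates (no near-collinearity)."""
    b = rng.uniform(0.8, 1.8, size=max(0, n_atoms - 1))
    theta = rng.uniform(50.0 * DEG, 130.0 * DEG, size=max(0, n_atoms - 2))
    phi = rng.uniform(-math.pi, math.pi, size=max(0, n_atoms - 3))
    return InternalCoordinates(b, theta, phi)
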