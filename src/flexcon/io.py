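"""File formats: Z-matrix (Gaussian-dialect text), XYZ, force-field YAML,
run configuration and report writers.

Angles are degrees and lengths Å in every file; conversion to radians
happens here and nowhere else.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .toy import DoubleWellTerm, HarmonicTerm, SyntheticFFParams, TorsionTerm
from .zmatrix import (
    CoordinateSplit,
    FrameConvention,
    InternalCoordinates,
    PrimedCoordinates,
    ZMatrixTopology,
    validate_topology,
)

__all__ = [
    "ZMatrixParseError",
    "read_zmatrix",
    "write_zmatrix",
    "write_xyz",
    "read_ff_params",
    "write_ff_params",
    "RunConfig",
    "config_hash",
    "write_json_report",
]

DEG = math.pi / 180.0


class ZMatrixParseError(ValueError):
    """Malformed or invalid Z-matrix file (message carries the line number)."""


def read_zmatrix(path) -> tuple[ZMatrixTopology, InternalCoordinates, CoordinateSplit]:
    """Parse a Z-matrix file with its split annotation.

    Format: one atom per line — ``element [bond_ref b [angle_ref theta_deg
    [dihedral_ref phi_deg kind]]]``; '#' starts a comment; a line
    ``unconstrained: name1 name2 ...`` (after the atoms) declares the split.
    """
    path = Path(path)
    elements: list[str] = []
    bond_ref, angle_ref, dihedral_ref, kinds = {}, {}, {}, {}
    b, theta, phi = [], [], []
    unconstrained: list[str] | None = None

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower().startswith("unconstrained:"):
            unconstrained = line.split(":", 1)[1].split()
            continue
        tok = line.split()
        k = len(elements) + 1
        try:
            if k == 1:
                if len(tok) != 1:
                    raise ValueError("atom 1 takes no references")
                elements.append(tok[0])
            elif k == 2:
                elements.append(tok[0])
                bond_ref[k] = int(tok[1])
                b.append(float(tok[2]))
            elif k == 3:
                elements.append(tok[0])
                bond_ref[k] = int(tok[1])
                b.append(float(tok[2]))
                angle_ref[k] = int(tok[3])
                theta.append(float(tok[4]) * DEG)
            else:
                elements.append(tok[0])
                bond_ref[k] = int(tok[1])
                b.append(float(tok[2]))
                angle_ref[k] = int(tok[3])
                theta.append(float(tok[4]) * DEG)
                dihedral_ref[k] = int(tok[5])
                phi.append(float(tok[6]) * DEG)
                kinds[k] = tok[7] if len(tok) > 7 else "principal"
        except (IndexError, ValueError) as exc:
            raise ZMatrixParseError(f"{path.name}:{lineno}: malformed atom line: {raw!r} ({exc})")

    if not elements:
        raise ZMatrixParseError(f"{path.name}: no atoms found")
    topology = ZMatrixTopology(
        atom_count=len(elements),
        element_labels=tuple(elements),
        bond_ref=bond_ref,
        angle_ref=angle_ref,
        dihedral_ref=dihedral_ref,
        dihedral_kind=kinds,
    )
    errors = validate_topology(topology)
    if errors:
        raise ZMatrixParseError(f"{path.name}: invalid topology: " + "; ".join(errors))
    internals = InternalCoordinates(np.array(b), np.array(theta), np.array(phi))
    try:
        internals.validate()
    except ValueError as exc:
        raise ZMatrixParseError(f"{path.name}: invalid internal coordinates: {exc}")
    if unconstrained is None:
        raise ZMatrixParseError(f"{path.name}: missing 'unconstrained:' split annotation")
    try:
        split = CoordinateSplit.from_unconstrained(topology, unconstrained)
    except ValueError as exc:
        raise ZMatrixParseError(f"{path.name}: bad split annotation: {exc}")
    return topology, internals, split


def write_zmatrix(path, topology: ZMatrixTopology, internals: InternalCoordinates,
                  split: CoordinateSplit, comment: str = "") -> None:
    lines = []
    if comment:
        lines.append(f"# {comment}")
    n = topology.atom_count
    for k in range(1, n + 1):
        el = topology.element_labels[k - 1]
        if k == 1:
            lines.append(el)
        elif k == 2:
            lines.append(f"{el} {topology.bond_ref[k]} {internals.get('b2'):.10f}")
        elif k == 3:
            lines.append(
                f"{el} {topology.bond_ref[k]} {internals.get('b3'):.10f} "
                f"{topology.angle_ref[k]} {internals.get('theta3') / DEG:.10f}"
            )
        else:
            lines.append(
                f"{el} {topology.bond_ref[k]} {internals.get(f'b{k}'):.10f} "
                f"{topology.angle_ref[k]} {internals.get(f'theta{k}') / DEG:.10f} "
                f"{topology.dihedral_ref[k]} {internals.get(f'phi{k}') / DEG:.10f} "
                f"{topology.dihedral_kind[k]}"
            )
    lines.append("unconstrained: " + " ".join(split.unconstrained_ids))
    Path(path).write_text("\n".join(lines) + "\n")


def write_xyz(path, coords: PrimedCoordinates, elements, comment: str = "") -> None:
    """Standard XYZ: atom count, comment line, ``element x y z`` rows."""
    n = coords.atom_count
    lines = [str(n), comment.replace("\n", " ")]
    for k in range(1, n + 1):
        x, y, z = coords.atom(k)
        lines.append(f"{elements[k - 1]:<3s} {x: .10f} {y: .10f} {z: .10f}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# force-field parameters
# ---------------------------------------------------------------------------

def write_ff_params(path, params: SyntheticFFParams) -> None:
    doc: dict = {
        "harmonic": {
            name: {
                "k": term.k,
                "q0": term.q0,
                **({"couplings": dict(term.couplings)} if term.couplings else {}),
                **({"wrap": True} if term.wrap else {}),
            }
            for name, term in params.harmonic.items()
        },
        "torsion": {
            name: [{"v": v, "n": n, "gamma": g} for v, n, g in term.terms]
            for name, term in params.torsion.items()
        },
    }
    if params.cross:
        doc["cross"] = [[a, b, k] for a, b, k in params.cross]
    if params.double_well is not None:
        dw = params.double_well
        doc["double_well"] = {
            "coord": params.double_well_coord,
            "barrier": dw.barrier,
            "width": dw.width,
            "q0": dw.q0,
            "tilt": dw.tilt,
            "partner": dw.partner,
        }
    doc["seed"] = params.seed
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_ff_params(path) -> SyntheticFFParams:
    doc = yaml.safe_load(Path(path).read_text())
    harmonic = {
        name: HarmonicTerm(
            k=float(spec["k"]),
            q0=float(spec["q0"]),
            couplings={str(k): float(v) for k, v in spec.get("couplings", {}).items()},
            wrap=bool(spec.get("wrap", False)),
        )
        for name, spec in doc.get("harmonic", {}).items()
    }
    torsion = {
        name: TorsionTerm([(float(t["v"]), int(t["n"]), float(t["gamma"])) for t in terms])
        for name, terms in doc.get("torsion", {}).items()
    }
    cross = [(str(a), str(b), float(k)) for a, b, k in doc.get("cross", [])]
    dw_spec = doc.get("double_well")
    dw = None
    dw_coord = None
    if dw_spec:
        dw_coord = str(dw_spec["coord"])
        dw = DoubleWellTerm(
            barrier=float(dw_spec["barrier"]),
            width=float(dw_spec["width"]),
            q0=float(dw_spec["q0"]),
            tilt=float(dw_spec["tilt"]),
            partner=str(dw_spec["partner"]),
        )
    return SyntheticFFParams(
        harmonic=harmonic, torsion=torsion, cross=cross,
        double_well=dw, double_well_coord=dw_coord, seed=int(doc.get("seed", 0)),
    )


# ---------------------------------------------------------------------------
# run configuration and reports
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """User-facing run settings; flag overrides beat file values beat these
    defaults.  Angle quantities (deltas) are degrees at this surface."""

    gtol: float = 1e-10
    max_iter: int = 500
    deltas_deg: tuple[float, ...] = (1e-3, 1e-2, 0.05, 0.1, 0.5, 1.0, 5.0, 10.0)
    scheme: str = "forward"
    frame: str = "z-xz"
    truncate_decimals: int | None = None
    seed: int = 0
    hop_threshold: float = 0.5

    def __post_init__(self):
        if self.gtol <= 0 or self.hop_threshold <= 0:
            raise ValueError("tolerances must be positive")
        deltas = tuple(float(d) for d in self.deltas_deg)
        if any(d <= 0 for d in deltas) or len(set(deltas)) != len(deltas):
            raise ValueError("delta values must be positive and unique")
        self.deltas_deg = deltas
        if self.scheme not in ("forward", "central"):
            raise ValueError("scheme must be forward or central")

    @property
    def frame_convention(self) -> FrameConvention:
        return FrameConvention.from_name(self.frame)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["deltas_deg"] = list(self.deltas_deg)
        return d


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_json_report(path, payload: dict, config: RunConfig | None = None) -> None:
    """JSON report stamped with the config hash and seed so every number in
    it is recomputable."""
    doc = dict(payload)
    if config is not None:
        doc["_config"] = config.to_dict()
        doc["_config_hash"] = config_hash(config)
        doc["_seed"] = config.seed
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True, default=_default) + "\n")
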