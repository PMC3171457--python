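import numpy as np
import pytest

from flexcon.toy import fixture_molecule
from flexcon.zmatrix import InternalCoordinates, ZMatrixTopology, build_cartesian


def make_topology(rows, elements=None):
    """rows: (bond_ref, angle_ref, dihedral_ref, kind) per atom 2..N."""
    n = len(rows) + 1
    bond_ref, angle_ref, dihedral_ref, kinds = {}, {}, {}, {}
    for k, (a, g, dref, kind) in enumerate(rows, start=2):
        bond_ref[k] = a
        if g is not None:
            angle_ref[k] = g
        if dref is not None:
            dihedral_ref[k] = dref
            kinds[k] = kind
    return ZMatrixTopology(
        atom_count=n,
        element_labels=tuple(elements or ["C"] * n),
        bond_ref=bond_ref,
        angle_ref=angle_ref,
        dihedral_ref=dihedral_ref,
        dihedral_kind=kinds,
    )


def linear_chain(n):
    """Unbranched chain 1-2-...-n with default references."""
    rows = []
    for k in range(2, n + 1):
        if k == 2:
            rows.append((1, None, None, None))
        elif k == 3:
            rows.append((2, 1, None, None))
        else:
            rows.append((k - 1, k - 2, k - 3, "principal"))
    return make_topology(rows)


@pytest.fixture
def branched8():
    """8-atom branched topology used as a worked example in docs/methods.md:
    a branch at atom 3 (principal atom 4, phase atom 5), one root-protocol
    atom (6), and continuations on both branches (7, 8)."""
    return make_topology(
        [
            (1, None, None, None),   # 2
            (2, 1, None, None),      # 3
            (3, 2, 1, "principal"),  # 4
            (3, 2, 4, "phase"),      # 5
            (2, 3, 1, "phase"),      # 6
            (5, 3, 2, "principal"),  # 7
            (4, 3, 2, "principal"),  # 8
        ]
    )


@pytest.fixture
def branched8_internals(branched8):
    rng = np.random.default_rng(88)
    from flexcon.toy import random_internals

    return random_internals(rng, branched8.atom_count)


@pytest.fixture(scope="session")
def methanol():
    return fixture_molecule("methanol_like")


@pytest.fixture(scope="session")
def nma():
    return fixture_molecule("nma_like")


@pytest.fixture(scope="session")
def gly3():
    return fixture_molecule("gly3_like")


def fd_position_jacobian(topology, internals, delta=1e-6):
    """Central-difference oracle for d x'_beta / d q over all coordinates,
    returned as an (N, 3, K) array in canonical coordinate order."""
    names = topology.coordinate_names()
    out = np.zeros((topology.atom_count, 3, len(names)))
    for j, nm in enumerate(names):
        plus = internals.copy()
        plus.set(nm, internals.get(nm) + delta / 2)
        minus = internals.copy()
        minus.set(nm, internals.get(nm) - delta / 2)
        out[:, :, j] = (build_cartesian(topology, plus).xyz - build_cartesian(topology, minus).xyz) / delta
    return out
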