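"""Topology validation, chains, special cases, and the Cartesian build /
measure round trip."""

import math

import numpy as np
import pytest

from flexcon.zmatrix import (
    CoordinateSplit,
    DegenerateGeometryError,
    FrameConvention,
    InternalCoordinates,
    build_cartesian,
    chain_to_origin,
    detect_special_cases,
    measure_internals,
    validate_topology,
    wrap_angle,
)
from flexcon.toy import random_internals, random_topology

from conftest import fd_position_jacobian, linear_chain, make_topology

DEG = math.pi / 180.0


class TestValidation:
    def test_canonical_chain_is_valid(self):
        assert validate_topology(linear_chain(4)) == []
        assert validate_topology(linear_chain(8)) == []

    def test_forward_reference_is_reported(self):
        topo = make_topology(
            [
                (1, None, None, None),
                (2, 1, None, None),
                (3, 2, 1, "principal"),
                (6, 3, 2, "principal"),  # atom 5 references atom 6
                (5, 4, 3, "principal"),
            ]
        )
        report = validate_topology(topo)
        assert any("forward reference at atom 5" in v for v in report)

    def test_duplicate_principal_on_bond_is_reported(self):
        topo = make_topology(
            [
                (1, None, None, None),
                (2, 1, None, None),
                (3, 2, 1, "principal"),
                (3, 2, 1, "principal"),  # second principal over bond (3, 2)
            ]
        )
        report = validate_topology(topo)
        assert any("principal dihedrals over bond (3, 2)" in v for v in report)

    def test_one_principal_rule_on_enumerated_toys(self):
        # exhaustive over kind assignments of two same-bond branch atoms:
        # exactly the principal/principal combination must fail
        for k4, k5, ok in [
            ("principal", "phase", True),
            ("principal", "principal", False),
        ]:
            dref5 = 4 if k5 == "phase" else 1
            topo = make_topology(
                [
                    (1, None, None, None),
                    (2, 1, None, None),
                    (2, 3, 1, k4),
                    (2, 3, dref5, k5),
                ]
            )
            assert (validate_topology(topo) == []) is ok, (k4, k5)

    def test_repeated_references_reported(self):
        topo = make_topology(
            [
                (1, None, None, None),
                (2, 2, None, None),
            ]
        )
        assert any("repeated reference" in v for v in validate_topology(topo))

    def test_nondefault_angle_reference_rejected(self):
        topo = make_topology(
            [
                (1, None, None, None),
                (2, 1, None, None),
                (3, 2, 1, "principal"),
                (4, 2, 3, "principal"),  # angle ref should be a(4)=... default 3
            ]
        )
        # atom 5: a=4, default angle ref a(4)=3, given 2 -> violation
        assert any("atom 5" in v and "angle reference" in v for v in validate_topology(topo))

    def test_child_of_root_protocol_atom_rejected(self):
        topo = make_topology(
            [
                (1, None, None, None),
                (2, 1, None, None),
                (2, 3, 1, "principal"),  # 4: root-protocol (terminal)
                (4, 2, 3, "principal"),  # 5 bonded to 4 -> invalid
            ]
        )
        assert any("terminal" in v for v in validate_topology(topo))


class TestChains:
    def test_root(self):
        assert chain_to_origin(linear_chain(4), 1) == [1]

    def test_linear_chain(self):
        assert chain_to_origin(linear_chain(4), 4) == [4, 3, 2, 1]

    def test_bad_index_raises(self):
        with pytest.raises(IndexError):
            chain_to_origin(linear_chain(4), 5)

    def test_agrees_with_graph_traversal(self, branched8):
        # independent oracle: BFS path in the undirected bond graph; in a
        # tree the unique path from k to 1 is the chain
        import collections

        adj = collections.defaultdict(set)
        for k, a in branched8.bond_ref.items():
            adj[k].add(a)
            adj[a].add(k)
        for k in branched8.atoms():
            prev = {1: None}
            queue = collections.deque([1])
            while queue:
                v = queue.popleft()
                for w in adj[v]:
                    if w not in prev:
                        prev[w] = v
                        queue.append(w)
            path = [k]
            while path[-1] != 1:
                path.append(prev[path[-1]])
            assert chain_to_origin(branched8, k) == path


class TestSpecialCases:
    def test_linear_chain_has_none(self):
        assert detect_special_cases(linear_chain(6)) == []

    def test_methanol_fig4a_entries(self, methanol):
        topo = methanol[0]
        a_cases = [c for c in detect_special_cases(topo) if c.tag == "fig4a_angle"]
        assert [(c.mover, c.owner) for c in a_cases] == [(4, 3), (5, 3), (6, 3)]

    def test_nma_fig4b_entry_at_carbonyl_branch(self, nma):
        topo = nma[0]
        b_cases = {(c.mover, c.owner) for c in detect_special_cases(topo) if c.tag == "fig4b_dihedral"}
        assert (5, 4) in b_cases  # the branch start references the principal atom

    @pytest.mark.parametrize("fixture_name", ["methanol", "nma"])
    def test_agrees_with_numeric_motion_oracle(self, fixture_name, request):
        # (beta, k) with k outside C(beta) is reported iff some internal of k
        # visibly moves beta
        topo, internals, _, _ = request.getfixturevalue(fixture_name)
        reported = {(c.mover, c.owner) for c in detect_special_cases(topo)}
        dense = fd_position_jacobian(topo, internals, delta=1e-5)
        names = topo.coordinate_names()
        observed = set()
        for beta in topo.atoms():
            chain = set(chain_to_origin(topo, beta))
            for j, nm in enumerate(names):
                k = topo.coordinate_owner(nm)
                if k in chain:
                    continue
                if np.max(np.abs(dense[beta - 1, :, j])) * 1e-5 > 1e-9:
                    observed.add((beta, k))
        assert reported == observed


class TestBuildMeasure:
    def test_two_atoms_on_frame_axis(self):
        topo = linear_chain(2)
        ints = InternalCoordinates([1.5], [], [])
        coords = build_cartesian(topo, ints)
        assert np.array_equal(coords.atom(1), [0.0, 0.0, 0.0])
        assert np.array_equal(coords.atom(2), [0.0, 0.0, 1.5])

    def test_three_atoms_right_angle_in_plane(self):
        topo = linear_chain(3)
        ints = InternalCoordinates([1.0, 1.0], [math.pi / 2], [])
        coords = build_cartesian(topo, ints)
        # atom 3 at unit distance from atom 2, right angle at atom 2,
        # in-plane (y = 0 exactly) with positive x
        np.testing.assert_allclose(coords.atom(3), [1.0, 0.0, 1.0], atol=1e-15)

    def test_gauge_zeros_are_exact(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(3, 10))
            topo = random_topology(rng, n)
            coords = build_cartesian(topo, random_internals(rng, n))
            assert np.all(coords.atom(1) == 0.0)
            assert coords.atom(2)[0] == 0.0 and coords.atom(2)[1] == 0.0
            assert coords.atom(3)[1] == 0.0 and coords.atom(3)[0] > 0.0

    def test_round_trip_many_random_molecules(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(3, 13))
            topo = random_topology(rng, n)
            ints = random_internals(rng, n)
            back = measure_internals(topo, build_cartesian(topo, ints))
            np.testing.assert_allclose(back.b, ints.b, atol=1e-10)
            np.testing.assert_allclose(back.theta, ints.theta, atol=1e-10)
            if n > 3:
                dphi = wrap_angle(back.phi - ints.phi)
                np.testing.assert_allclose(dphi, 0.0, atol=1e-10)

    def test_cis_arrangement_measures_zero_dihedral(self):
        topo = linear_chain(4)
        ints = InternalCoordinates([1.0, 1.0, 1.0], [100 * DEG, 100 * DEG], [0.0])
        coords = build_cartesian(topo, ints)
        measured = measure_internals(topo, coords)
        assert abs(measured.phi[0]) < 1e-12
        # and the four atoms are coplanar with atoms 1, 4 on the same side
        assert abs(coords.atom(4)[1]) < 1e-12

    def test_isometry_invariance_after_regauge(self):
        # rotating + translating the molecule rigidly, then re-expressing it
        # in the body frame, leaves all internals unchanged
        rng = np.random.default_rng(7)
        from scipy.spatial.transform import Rotation

        for _ in range(10):
            n = int(rng.integers(4, 10))
            topo = random_topology(rng, n)
            ints = random_internals(rng, n)
            xyz = build_cartesian(topo, ints).xyz
            R = Rotation.random(rng=rng).as_matrix()
            moved = xyz @ R.T + rng.normal(size=3)
            from flexcon.zmatrix import PrimedCoordinates

            back = measure_internals(topo, PrimedCoordinates(moved))
            np.testing.assert_allclose(back.b, ints.b, atol=1e-9)
            np.testing.assert_allclose(back.theta, ints.theta, atol=1e-9)
            if n > 3:
                np.testing.assert_allclose(wrap_angle(back.phi - ints.phi), 0.0, atol=1e-9)

    def test_collinear_reference_triplet_raises(self):
        topo = linear_chain(4)
        ints = InternalCoordinates([1.0, 1.0, 1.0], [math.pi / 2, math.pi / 2], [0.0])
        ints.theta[0] = 1e-14  # atoms 1-2-3 collinear
        with pytest.raises((DegenerateGeometryError, ValueError)):
            build_cartesian(topo, ints)

    def test_alternate_frame_convention_round_trips(self):
        frame = FrameConvention.from_name("x-xy")
        rng = np.random.default_rng(11)
        topo = random_topology(rng, 7)
        ints = random_internals(rng, 7)
        coords = build_cartesian(topo, ints, frame)
        assert coords.atom(2)[1] == 0.0 and coords.atom(2)[2] == 0.0  # on +x
        assert coords.atom(3)[2] == 0.0  # in xy-plane
        back = measure_internals(topo, coords)
        np.testing.assert_allclose(back.b, ints.b, atol=1e-10)
        np.testing.assert_allclose(wrap_angle(back.phi - ints.phi), 0.0, atol=1e-10)


class TestSplit:
    def test_split_partition_enforced(self, methanol):
        topo = methanol[0]
        with pytest.raises(ValueError):
            CoordinateSplit.from_unconstrained(topo, ["phi99"])
        split = CoordinateSplit.from_unconstrained(topo, ["phi4"])
        assert split.m == 1 and split.l == topo.n_internals - 1
        assert set(split.unconstrained_ids) | set(split.constrained_ids) == set(topo.coordinate_names())
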