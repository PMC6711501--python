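"""Explicit-Coulomb field maps: kernel, grids, averaging, differences."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulsefield.constants import COULOMB_E_NM
from pulsefield.core import Frame, Trajectory
from pulsefield.fieldmaps import (
    build_active_site_frame,
    coulomb_field,
    difference_map,
    evaluate_field_map,
    export_map,
    make_grid,
)
from pulsefield.synthetic import make_point_charge_fixture


def brute_force_field(node, positions, charges, exclusion_radius=0.0):
    """Independent double-loop Coulomb oracle."""
    e = np.zeros(3)
    for r_n, q in zip(positions, charges):
        d = np.asarray(node, float) - np.asarray(r_n, float)
        dist = np.sqrt(np.sum(d**2))
        if dist <= exclusion_radius:
            continue
        e += COULOMB_E_NM * q * d / dist**3
    return e


class TestActiveSiteFrame:
    def test_canonical_axes(self):
        f = build_active_site_frame([0, 0, 0], [1, 0, 0], [0, 1, 0])
        np.testing.assert_allclose(f.x_axis, [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(f.in_plane_axis, [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(f.normal_axis, [0, 0, 1], atol=1e-12)

    def test_collinear_anchors_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            build_active_site_frame([0, 0, 0], [1, 0, 0], [2, 0, 0])

    def test_coincident_anchors_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            build_active_site_frame([0, 0, 0], [0, 0, 0], [0, 1, 0])

    @settings(max_examples=50, deadline=None)
    @given(data=st.data())
    def test_orthonormal_for_random_anchors(self, data):
        coords = data.draw(
            st.lists(
                st.floats(-5, 5, allow_nan=False).map(lambda v: round(v, 3)),
                min_size=9, max_size=9,
            )
        )
        cu, o2, zn = np.array(coords).reshape(3, 3)
        try:
            f = build_active_site_frame(cu, o2, zn)
        except ValueError:
            return  # degenerate draw
        axes = np.array([f.x_axis, f.in_plane_axis, f.normal_axis])
        np.testing.assert_allclose(axes @ axes.T, np.eye(3), atol=1e-9)
        # right-handed
        np.testing.assert_allclose(
            np.cross(f.x_axis, f.in_plane_axis), f.normal_axis, atol=1e-9
        )


class TestMakeGrid:
    def test_study_grid_node_count(self):
        f = build_active_site_frame([0, 0, 0], [1, 0, 0], [0, 1, 0])
        grid = make_grid(f, "pi_doubleprime", extent=4.7, spacing=0.05)
        assert grid.n_per_side == 95
        assert grid.nodes.shape == (9025, 3)

    def test_center_node_is_origin(self):
        cu = np.array([2.0, 3.0, 4.0])
        f = build_active_site_frame(cu, cu + [1, 0, 0], cu + [0, 1, 0])
        grid = make_grid(f, "pi_prime", extent=0.1, spacing=0.05)
        assert grid.nodes.shape == (9, 3)
        center = grid.nodes[np.argmin(np.linalg.norm(grid.local_uv, axis=1))]
        np.testing.assert_allclose(center, cu, atol=1e-12)

    def test_anchor_plane_contains_all_three_anchors(self):
        cu = np.array([1.0, 1.0, 1.0])
        o2 = np.array([1.7, 1.2, 0.9])
        zn = np.array([0.8, 1.9, 1.4])
        f = build_active_site_frame(cu, o2, zn)
        grid = make_grid(f, "pi_doubleprime", extent=1.0, spacing=0.1)
        normal = f.normal_axis
        for point in grid.nodes:
            assert abs(np.dot(point - cu, normal)) < 1e-9
        for anchor in (cu, o2, zn):
            assert abs(np.dot(anchor - cu, normal)) < 1e-9

    def test_planes_are_orthogonal(self):
        f = build_active_site_frame([0, 0, 0], [1, 1, 0], [0, 1, 1])
        # pi'' normal is normal_axis; pi' normal is in_plane_axis
        assert abs(np.dot(f.normal_axis, f.in_plane_axis)) < 1e-12

    def test_non_integer_cell_count_rejected(self):
        f = build_active_site_frame([0, 0, 0], [1, 0, 0], [0, 1, 0])
        with pytest.raises(ValueError, match="integer"):
            make_grid(f, "pi_prime", extent=1.0, spacing=0.03)


class TestCoulombField:
    def test_single_unit_charge_closed_form(self):
        e, excluded = coulomb_field([1, 0, 0], [[0, 0, 0]], [1.0])
        np.testing.assert_allclose(e, [COULOMB_E_NM, 0, 0], rtol=1e-12)
        assert excluded == 0

    def test_empty_atom_set(self):
        e, excluded = coulomb_field([0, 0, 0], np.empty((0, 3)), [])
        np.testing.assert_array_equal(e, [0, 0, 0])
        assert excluded == 0

    def test_symmetric_pair_cancels(self):
        e, _ = coulomb_field(
            [0, 0, 0], [[-1, 0, 0], [1, 0, 0]], [1.0, 1.0]
        )
        np.testing.assert_allclose(e, [0, 0, 0], atol=1e-3)

    def test_inverse_square_decay(self):
        e1, _ = coulomb_field([1, 0, 0], [[0, 0, 0]], [1.0])
        e2, _ = coulomb_field([2, 0, 0], [[0, 0, 0]], [1.0])
        ratio = np.linalg.norm(e1) / np.linalg.norm(e2)
        assert ratio == pytest.approx(4.0, rel=1e-12)

    def test_vectorized_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        positions = rng.uniform(0, 2, (100, 3))
        charges = rng.choice([-1.0, -0.5, 0.5, 1.0], 100)
        nodes = rng.uniform(0, 2, (100, 3))
        for node in nodes:
            expected = brute_force_field(node, positions, charges,
                                         exclusion_radius=0.05)
            actual, _ = coulomb_field(node, positions, charges,
                                      exclusion_radius=0.05)
            np.testing.assert_allclose(actual, expected, rtol=1e-9,
                                       atol=1e-9 * COULOMB_E_NM)

    def test_exclusion_radius_counts(self):
        e, excluded = coulomb_field(
            [0, 0, 0], [[0.01, 0, 0], [1, 0, 0]], [1.0, 1.0],
            exclusion_radius=0.05,
        )
        assert excluded == 1
        np.testing.assert_allclose(e, [-COULOMB_E_NM, 0, 0], rtol=1e-12)


def _trajectory_from_fixture(n=24, seed=2, species=("protein", "water", "ion")):
    topo, frame = make_point_charge_fixture(n, box=(3, 3, 3), seed=seed)
    from pulsefield.core import Topology, update_atom

    atoms = [
        update_atom(a, species=species[i % len(species)])
        for i, a in enumerate(topo)
    ]
    topo = Topology(atoms)
    return Trajectory(topology=topo, frames=[frame])


class TestEvaluateFieldMap:
    def _grid(self, extent=0.4, spacing=0.1):
        f = build_active_site_frame([1.5, 1.5, 1.5], [2.5, 1.5, 1.5],
                                    [1.5, 2.5, 1.5])
        return make_grid(f, "pi_doubleprime", extent=extent, spacing=spacing)

    def test_species_superposition(self):
        traj = _trajectory_from_fixture()
        fmap = evaluate_field_map(traj, self._grid())
        total = sum(fmap.E_by_species.values())
        np.testing.assert_allclose(fmap.E_total, total, rtol=1e-12)

    def test_total_matches_single_sum_oracle(self):
        traj = _trajectory_from_fixture()
        fmap = evaluate_field_map(traj, self._grid(), exclusion_radius=0.05)
        frame = traj.frames[0]
        for k, node in enumerate(self._grid().nodes):
            expected = brute_force_field(
                node, frame.positions, traj.topology.charges,
                exclusion_radius=0.05,
            )
            np.testing.assert_allclose(
                fmap.E_total[k], expected, rtol=1e-9,
                atol=1e-9 * COULOMB_E_NM,
            )

    def test_charge_doubling_doubles_field(self):
        traj = _trajectory_from_fixture()
        from pulsefield.core import Topology, update_atom

        doubled = Topology(
            [update_atom(a, charge=2 * a.charge) for a in traj.topology]
        )
        traj2 = Trajectory(topology=doubled, frames=traj.frames)
        m1 = evaluate_field_map(traj, self._grid())
        m2 = evaluate_field_map(traj2, self._grid())
        np.testing.assert_allclose(m2.E_total, 2 * m1.E_total, rtol=1e-12)

    def test_rotation_equivariance(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(4)
        rot = Rotation.random(rng=rng)
        topo, frame = make_point_charge_fixture(10, box=(2, 2, 2), seed=9)
        anchors = np.array([[1, 1, 1], [1.5, 1, 1], [1, 1.6, 1]], float)
        f1 = build_active_site_frame(*anchors)
        g1 = make_grid(f1, "pi_doubleprime", extent=0.2, spacing=0.1)
        t1 = Trajectory(topology=topo, frames=[frame])
        m1 = evaluate_field_map(t1, g1, exclusion_radius=0.01)

        frame2 = Frame(time=0.0, positions=rot.apply(frame.positions))
        f2 = build_active_site_frame(*(rot.apply(anchors)))
        g2 = make_grid(f2, "pi_doubleprime", extent=0.2, spacing=0.1)
        t2 = Trajectory(topology=topo, frames=[frame2])
        m2 = evaluate_field_map(t2, g2, exclusion_radius=0.01)
        np.testing.assert_allclose(
            m2.E_total, rot.apply(m1.E_total), rtol=1e-8,
            atol=1e-9 * COULOMB_E_NM,
        )

    def test_minimum_image_translation_invariance(self):
        topo, frame = make_point_charge_fixture(12, box=(3, 3, 3), seed=5)
        traj = Trajectory(topology=topo, frames=[frame])
        shifted = Frame(
            time=0.0,
            positions=frame.positions + np.array([3.0, 0.0, 0.0]),
            box=frame.box,
        )
        traj2 = Trajectory(topology=topo, frames=[shifted])
        grid = self._grid()
        m1 = evaluate_field_map(traj, grid, pbc="minimum_image")
        m2 = evaluate_field_map(traj2, grid, pbc="minimum_image")
        np.testing.assert_allclose(m2.E_total, m1.E_total, rtol=1e-9)

    def test_frame_averaging_counts(self):
        traj = _trajectory_from_fixture()
        frame2 = Frame(time=1.0, positions=traj.frames[0].positions + 0.1,
                       box=traj.frames[0].box)
        traj = Trajectory(topology=traj.topology,
                          frames=[traj.frames[0], frame2])
        fmap = evaluate_field_map(traj, self._grid())
        assert fmap.frames_averaged == 2
        m1 = evaluate_field_map(traj, self._grid(), frames=range(0, 1))
        m2 = evaluate_field_map(traj, self._grid(), frames=range(1, 2))
        np.testing.assert_allclose(
            fmap.E_total, 0.5 * (m1.E_total + m2.E_total), rtol=1e-12
        )

    def test_empty_frame_selection_errors(self):
        traj = _trajectory_from_fixture()
        with pytest.raises(ValueError, match="empty"):
            evaluate_field_map(traj, self._grid(), frames=range(0, 0))

    def test_uncharged_topology_warns_zero_map(self):
        from pulsefield.core import Topology, update_atom

        traj = _trajectory_from_fixture()
        zero = Topology([update_atom(a, charge=0.0) for a in traj.topology])
        traj0 = Trajectory(topology=zero, frames=traj.frames)
        with pytest.warns(UserWarning, match="zero"):
            fmap = evaluate_field_map(traj0, self._grid())
        np.testing.assert_array_equal(fmap.E_total, 0.0)


class TestDifferenceAndExport:
    def _map(self, seed=2):
        traj = _trajectory_from_fixture(seed=seed)
        f = build_active_site_frame([1.5, 1.5, 1.5], [2.5, 1.5, 1.5],
                                    [1.5, 2.5, 1.5])
        grid = make_grid(f, "pi_doubleprime", extent=0.2, spacing=0.1)
        return evaluate_field_map(traj, grid)

    def test_self_difference_is_zero(self):
        m = self._map()
        d = difference_map(m, m)
        np.testing.assert_array_equal(d.E_total, 0.0)

    def test_species_differences_sum_to_total_difference(self):
        a, b = self._map(seed=2), self._map(seed=3)
        d = difference_map(a, b)
        np.testing.assert_allclose(
            sum(d.E_by_species.values()), d.E_total, rtol=1e-12
        )

    def test_mask_union(self):
        a, b = self._map(seed=2), self._map(seed=3)
        d = difference_map(a, b)
        np.testing.assert_array_equal(d.mask, a.mask | b.mask)

    def test_grid_mismatch_rejected(self):
        a = self._map()
        f = build_active_site_frame([0, 0, 0], [1, 0, 0], [0, 1, 0])
        other_grid = make_grid(f, "pi_doubleprime", extent=0.2, spacing=0.1)
        traj = _trajectory_from_fixture()
        b = evaluate_field_map(traj, other_grid)
        with pytest.raises(ValueError, match="grids"):
            difference_map(a, b)

    def test_export_row_count_and_round_trip(self, tmp_path):
        import pandas as pd

        m = self._map()
        path = tmp_path / "map.tsv"
        export_map(m, path)
        table = pd.read_csv(path, sep="\t")
        # 3x3 grid -> 9 rows for each of protein/water/ion/total
        assert len(table) == 9 * 4
        total = table[table.species == "total"]
        np.testing.assert_allclose(
            total[["Ex_V_per_m", "Ey_V_per_m", "Ez_V_per_m"]].to_numpy(),
            m.E_total, rtol=1e-6,
        )
        assert "mask" in table.columns
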