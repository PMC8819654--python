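"""Hydration-shell assignment, Voronoi volumes, density and intrinsic field."""

import numpy as np
import pytest

from conftest import frame_from_positions, two_site_dipole_topology
from hydrodipole.dipoles import Topology, Trajectory
from hydrodipole.shells import (
    BULK,
    SHELL1,
    SHELL2,
    assign_shells,
    coulomb_field,
    density_profile,
    intrinsic_field_distribution,
    periodic_voronoi_volumes,
    surface_distance,
    voronoi_shell_volumes,
)


def _protein_plus_waters(protein_xyz, water_xyz, box=100.0):
    """One carbon 'protein' per row of protein_xyz plus ±q-pair waters."""
    protein_xyz = np.atleast_2d(protein_xyz)
    water_xyz = np.atleast_2d(water_xyz)
    topo = two_site_dipole_topology(
        len(water_xyz), dipole_d=2.0, extra_protein_sites=len(protein_xyz)
    )
    pos = [protein_xyz]
    for w in water_xyz:
        pos.append([w, w + np.array([0.3, 0, 0])])
    frame = frame_from_positions(np.vstack(pos), box=box)
    return frame, topo


class TestSurfaceDistance:
    def test_single_pair(self):
        frame, topo = _protein_plus_waters([[0, 0, 0]], [[5.0, 0, 0]])
        assert surface_distance(frame, topo, 1) == pytest.approx(5.0)

    def test_coincident_is_zero(self):
        frame, topo = _protein_plus_waters([[2, 2, 2]], [[2.0, 2, 2]])
        assert surface_distance(frame, topo, 1) == pytest.approx(0.0)

    def test_minimum_rule(self):
        frame, topo = _protein_plus_waters([[0, 0, 0], [3, 0, 0]], [[4.0, 0, 0]])
        assert surface_distance(frame, topo, 1) == pytest.approx(1.0)

    def test_periodic_image_distance(self):
        frame, topo = _protein_plus_waters([[1, 1, 1]], [[19.0, 1, 1]], box=20.0)
        assert surface_distance(frame, topo, 1) == pytest.approx(2.0)

    def test_no_protein_atoms_errors(self):
        topo = two_site_dipole_topology(1)
        frame = frame_from_positions([[0, 0, 0], [0.3, 0, 0]])
        with pytest.raises(ValueError, match="no protein heavy atoms"):
            surface_distance(frame, topo, 0)


class TestAssignShells:
    @pytest.mark.parametrize(
        "distance, label", [(1.0, SHELL1), (2.25, SHELL1), (3.0, SHELL2),
                            (6.0, SHELL2), (7.0, BULK)]
    )
    def test_boundary_labels(self, distance, label):
        frame, topo = _protein_plus_waters([[0, 0, 0]], [[distance, 0, 0]])
        a = assign_shells(frame, topo)
        assert a.labels[0] == label

    def test_partition_complete_and_idempotent(self):
        rng = np.random.default_rng(1)
        frame, topo = _protein_plus_waters(
            [[50, 50, 50]], rng.uniform(40, 60, size=(30, 3))
        )
        a1 = assign_shells(frame, topo)
        a2 = assign_shells(frame, topo)
        assert sum(a1.counts().values()) == 30
        np.testing.assert_array_equal(a1.labels, a2.labels)
        np.testing.assert_allclose(a1.surface_distances, a2.surface_distances)

    def test_invalid_boundaries(self):
        frame, topo = _protein_plus_waters([[0, 0, 0]], [[3.0, 0, 0]])
        with pytest.raises(ValueError):
            assign_shells(frame, topo, b1=6.0, b2=2.25)


class TestVoronoi:
    def test_single_seed_owns_whole_box(self):
        box = np.array([12.0, 9.0, 7.0])
        v = periodic_voronoi_volumes(np.array([[1.0, 2.0, 3.0]]), box)
        assert v[0] == pytest.approx(np.prod(box), rel=1e-9)

    def test_cubic_sublattice_equal_cells(self):
        box = np.full(3, 10.0)
        grid = np.array(
            [[x, y, z] for x in (2.5, 7.5) for y in (2.5, 7.5) for z in (2.5, 7.5)]
        )
        v = periodic_voronoi_volumes(grid, box)
        np.testing.assert_allclose(v, 1000.0 / 8, rtol=1e-9)

    def test_random_seeds_conserve_volume(self):
        box = np.array([20.0, 15.0, 18.0])
        pts = np.random.default_rng(3).uniform(0, 1, size=(120, 3)) * box
        v = periodic_voronoi_volumes(pts, box)
        assert v.sum() == pytest.approx(np.prod(box), rel=1e-3)
        assert np.all(v > 0)

    def test_degenerate_seeds_error_names_indices(self):
        pts = np.array([[1.0, 1, 1], [1.0, 1, 1], [5.0, 5, 5]])
        with pytest.raises(ValueError, match="degenerate"):
            periodic_voronoi_volumes(pts, np.full(3, 10.0))

    def test_shell_volumes_partition_water_volume(self):
        rng = np.random.default_rng(5)
        frame, topo = _protein_plus_waters(
            [[15.0, 15, 15]], rng.uniform(0, 30, size=(60, 3)), box=30.0
        )
        a = assign_shells(frame, topo)
        shells = voronoi_shell_volumes(frame, topo, a)
        assert a.voronoi_volumes is not None
        assert sum(shells.values()) == pytest.approx(
            a.voronoi_volumes.sum(), rel=1e-12
        )
        assert sum(shells.values()) < 30.0**3  # protein cell excluded


class TestDensityProfile:
    def test_zero_waters_all_zero(self):
        topo = Topology(
            charges=np.array([0.0]),
            masses=np.array([12.011]),
            mol_id=np.array([0]),
            mol_class=np.array(["protein"], dtype=object),
        )
        traj = Trajectory(
            times=np.array([0.0]),
            positions=np.array([[[5.0, 5, 5]]]),
            box=np.array([[10.0, 10, 10]]),
        )
        p = density_profile(traj, topo, bin_width=1.0, max_distance=5.0)
        np.testing.assert_array_equal(p.density, 0.0)

    def test_single_distance_single_bin(self):
        frame, topo = _protein_plus_waters(
            [[25.0, 25, 25]],
            [[29.0, 25, 25], [21.0, 25, 25], [25.0, 29, 25], [25.0, 21, 25]],
            box=50.0,
        )
        traj = Trajectory(
            times=np.array([0.0]),
            positions=frame.positions[None],
            box=frame.box[None],
        )
        p = density_profile(traj, topo, bin_width=1.0, max_distance=8.0)
        nz = np.flatnonzero(p.density)
        assert list(nz) == [4]  # all waters at distance 4 Å


class TestIntrinsicField:
    def test_unit_charge_at_one_angstrom(self):
        e = coulomb_field(
            np.array([1.0, 0, 0]),
            np.array([[0.0, 0, 0]]),
            np.array([1.0]),
            np.full(3, 100.0),
        )
        assert np.linalg.norm(e) == pytest.approx(14.3996, rel=1e-9)

    def test_no_charges_gives_zero(self):
        e = coulomb_field(
            np.array([1.0, 0, 0]), np.empty((0, 3)), np.empty(0), np.full(3, 50.0)
        )
        np.testing.assert_array_equal(e, 0.0)

    def test_symmetric_pair_cancels_transverse(self):
        # +q and −q symmetric about the evaluation point along x
        e = coulomb_field(
            np.array([0.0, 0, 0]),
            np.array([[2.0, 0, 0], [-2.0, 0, 0]]),
            np.array([1.0, -1.0]),
            np.full(3, 100.0),
        )
        assert abs(e[1]) < 1e-12 and abs(e[2]) < 1e-12
        assert e[0] == pytest.approx(-2 * 14.3996 / 4.0)

    def test_distribution_over_hydration_waters(self):
        frame, topo = _protein_plus_waters(
            [[10.0, 10, 10]], [[12.0, 10, 10], [10.0, 14, 10], [10.0, 10, 30.0]],
            box=60.0,
        )
        topo.charges[0] = 1.0  # charge the protein site
        a = assign_shells(frame, topo)
        mags, hist, edges = intrinsic_field_distribution(frame, topo, a, bins=10)
        # only the two hydration-layer waters contribute
        assert len(mags) == 2
        np.testing.assert_allclose(
            np.sort(mags), [14.3996 / 16.0, 14.3996 / 4.0], rtol=1e-9
        )
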