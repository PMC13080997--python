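"""Geometric interaction criteria, RDF normalisation, density overlap."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from allokin import (
    DensityGrid,
    GridSpec,
    Trajectory,
    density_overlap,
    hbond_series,
    occupancy_density,
    pi_stack_series,
    rdf,
    salt_bridge_series,
)
from allokin.synthetic_data import ca_chain_structure
from allokin.trajectory_io import Structure


def point_structure(coords, names=None):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return Structure(
        names=np.array(names if names is not None else ["C"] * n, dtype=object),
        resids=np.arange(1, n + 1),
        resnames=np.array(["LIG"] * n, dtype=object),
        chain_ids=np.array(["A"] * n, dtype=object),
        coords=coords,
    )


def hexagon(center, normal, radius=1.4):
    """Planar hexagon of 6 points around a center, perpendicular to normal."""
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    a = np.array([1.0, 0, 0]) if abs(normal[0]) < 0.9 else np.array([0, 1.0, 0])
    u = np.cross(normal, a)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    ang = np.linspace(0, 2 * np.pi, 6, endpoint=False)
    return center + radius * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))


class TestPiStack:
    def frame_traj(self, ring_a, ring_b):
        coords = np.concatenate([ring_a, ring_b])
        topo = point_structure(coords)
        return Trajectory(topo, coords[None]), np.arange(6), np.arange(6, 12)

    def test_parallel_stacked_pair(self):
        a = hexagon(np.zeros(3), [0, 0, 1.0])
        b = hexagon([0, 0, 3.5], [0, 0, 1.0])
        traj, ia, ib = self.frame_traj(a, b)
        series = pi_stack_series(traj, ia, ib)
        assert series.distance[0] == pytest.approx(3.5)
        assert series.angle[0] == pytest.approx(0.0, abs=1e-8)
        assert series.occupancy == 1.0

    def test_distant_rings_not_stacked(self):
        a = hexagon(np.zeros(3), [0, 0, 1.0])
        b = hexagon([0, 0, 10.0], [0, 0, 1.0])
        traj, ia, ib = self.frame_traj(a, b)
        assert pi_stack_series(traj, ia, ib).occupancy == 0.0

    def test_t_shaped_excluded(self):
        a = hexagon(np.zeros(3), [0, 0, 1.0])
        b = hexagon([0, 0, 4.0], [1.0, 0, 0])  # perpendicular plane
        traj, ia, ib = self.frame_traj(a, b)
        series = pi_stack_series(traj, ia, ib)
        assert series.angle[0] == pytest.approx(90.0)
        assert series.occupancy == 0.0

    def test_degenerate_ring_flagged_not_counted(self, rng):
        a = hexagon(np.zeros(3), [0, 0, 1.0])
        blob = rng.uniform(-1.5, 1.5, (6, 3)) + [0, 0, 3.5]  # no plane
        traj, ia, ib = self.frame_traj(a, blob)
        series = pi_stack_series(traj, ia, ib, planarity_max=0.1)
        assert not series.valid[0]
        assert series.occupancy == 0.0

    def test_small_ring_rejected(self):
        a = hexagon(np.zeros(3), [0, 0, 1.0])
        traj, ia, ib = self.frame_traj(a, a + [0, 0, 3.0])
        with pytest.raises(ValueError, match="5 atoms"):
            pi_stack_series(traj, ia[:3], ib)


class TestSaltBridge:
    def pair_traj(self, separations):
        topo = point_structure([[0.0, 0, 0], [1.0, 0, 0]])
        frames = np.zeros((len(separations), 2, 3))
        frames[:, 1, 0] = separations
        return Trajectory(topo, frames)

    def test_close_pair_full_occupancy(self):
        assert salt_bridge_series(self.pair_traj([3.0] * 4), [0], [1]).occupancy == 1.0

    def test_far_pair_zero_occupancy(self):
        assert salt_bridge_series(self.pair_traj([8.0] * 4), [0], [1]).occupancy == 0.0

    def test_alternating_half_occupancy(self):
        series = salt_bridge_series(self.pair_traj([3.0, 8.0] * 5), [0], [1])
        assert series.occupancy == pytest.approx(0.5)

    def test_minimum_cross_distance_used(self):
        # carboxylate with two oxygens: the nearer one defines the distance
        topo = point_structure([[0.0, 0, 0], [0.0, 2.0, 0], [3.0, 0, 0]])
        traj = Trajectory(topo, topo.coords[None])
        series = salt_bridge_series(traj, [0, 1], [2])
        assert series.distance[0] == pytest.approx(3.0)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            salt_bridge_series(self.pair_traj([3.0, 3.0]), [], [1])


class TestHbond:
    def dha_traj(self, d_pos, h_pos, a_pos):
        topo = point_structure([d_pos, h_pos, a_pos], names=["N", "H", "O"])
        return Trajectory(topo, topo.coords[None])

    def test_linear_short_bonded(self):
        traj = self.dha_traj([0, 0, 0], [1.0, 0, 0], [2.8, 0, 0])
        series = hbond_series(traj, [0], [1], [2])
        assert series.satisfied[0]
        assert series.angle[0] == pytest.approx(180.0)

    def test_long_distance_not_bonded(self):
        traj = self.dha_traj([0, 0, 0], [1.0, 0, 0], [5.0, 0, 0])
        assert hbond_series(traj, [0], [1], [2]).occupancy == 0.0

    def test_bent_geometry_not_bonded(self):
        # 90° at the hydrogen, D...A 2.8 Å
        d = [0.0, 0, 0]
        h = [1.98, 1.98, 0]
        a = [2.8, 0.0, 0]
        traj = self.dha_traj(d, h, a)
        series = hbond_series(traj, [0], [1], [2])
        assert series.distance[0] == pytest.approx(2.8)
        assert series.angle[0] < 135.0
        assert series.occupancy == 0.0

    def test_missing_hydrogen_hint(self):
        traj = self.dha_traj([0, 0, 0], [1, 0, 0], [2.8, 0, 0])
        with pytest.raises(ValueError, match="heavy-atom"):
            hbond_series(traj, [0], None, [2])


class TestOccupancyMonotonicity:
    """Occupancy must respond monotonically to its thresholds."""

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           d1=st.floats(2.0, 6.0), d2=st.floats(2.0, 6.0))
    def test_salt_bridge_occupancy_nondecreasing_in_dmax(self, seed, d1, d2):
        rng = np.random.default_rng(seed)
        topo = point_structure([[0.0, 0, 0], [1.0, 0, 0]])
        frames = np.zeros((30, 2, 3))
        frames[:, 1, 0] = rng.uniform(1.0, 9.0, 30)
        traj = Trajectory(topo, frames)
        lo, hi = sorted((d1, d2))
        occ_lo = salt_bridge_series(traj, [0], [1], d_max=lo).occupancy
        occ_hi = salt_bridge_series(traj, [0], [1], d_max=hi).occupancy
        assert 0.0 <= occ_lo <= occ_hi <= 1.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           a1=st.floats(90.0, 179.0), a2=st.floats(90.0, 179.0))
    def test_hbond_occupancy_nonincreasing_in_angle_min(self, seed, a1, a2):
        rng = np.random.default_rng(seed)
        frames = np.zeros((30, 3, 3))
        frames[:, 1] = [1.0, 0, 0]
        ang = rng.uniform(0.5 * np.pi, np.pi, 30)  # D-H...A angle
        frames[:, 2, 0] = 1.0 + 1.8 * np.cos(np.pi - ang)
        frames[:, 2, 1] = 1.8 * np.sin(np.pi - ang)
        topo = point_structure(frames[0], names=["N", "H", "O"])
        traj = Trajectory(topo, frames)
        lo, hi = sorted((a1, a2))
        occ_strict = hbond_series(traj, [0], [1], [2], angle_min=hi).occupancy
        occ_loose = hbond_series(traj, [0], [1], [2], angle_min=lo).occupancy
        assert 0.0 <= occ_strict <= occ_loose <= 1.0


class TestRDF:
    def test_uniform_gas_converges_to_one(self):
        # ~1e5 in-sphere samples; bins wide enough that every shell holds
        # thousands of counts, so a 0.05 max deviation is a >3 sigma bound
        rng = np.random.default_rng(77)
        box = 30.0
        n_target, n_frames = 18000, 50
        frames = np.empty((n_frames, 1 + n_target, 3))
        frames[:, 0] = box / 2
        frames[:, 1:] = rng.uniform(0, box, (n_frames, n_target, 3))
        topo = point_structure(frames[0])
        traj = Trajectory(topo, frames)
        profile = rdf(traj, [0], np.arange(1, 1 + n_target), r_max=9.0, bin_width=3.0)
        assert profile.counts.sum() >= 1e5
        assert np.abs(profile.g - 1.0).max() <= 0.05

    def test_single_rigid_pair_single_bin(self):
        topo = point_structure([[0.0, 0, 0], [3.0, 0, 0]])
        traj = Trajectory(topo, topo.coords[None].repeat(10, axis=0))
        profile = rdf(traj, [0], [1], r_max=5.0, bin_width=0.5)
        hot = np.flatnonzero(profile.counts)
        assert hot.size == 1
        assert profile.r[hot[0]] == pytest.approx(3.25)  # 3.0 falls in [3.0, 3.5)

    def test_normalisation_identity(self):
        # sum over bins of g * rho * shell_volume = mean targets within r_max
        rng = np.random.default_rng(8)
        frames = np.empty((20, 41, 3))
        frames[:, 0] = 25.0
        frames[:, 1:] = rng.uniform(0, 50, (20, 40, 3))
        topo = point_structure(frames[0])
        traj = Trajectory(topo, frames)
        profile = rdf(traj, [0], np.arange(1, 41), r_max=12.0, bin_width=1.0)
        edges = np.arange(0, 12.0 + 1.0, 1.0)
        shell_vol = 4 / 3 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        integral = np.sum(profile.g * profile.density * shell_vol)
        per_ref = profile.counts.sum() / (profile.n_frames * profile.n_reference)
        assert integral == pytest.approx(per_ref)

    def test_overlapping_selections_rejected(self):
        topo = point_structure([[0.0, 0, 0], [3.0, 0, 0]])
        traj = Trajectory(topo, topo.coords[None])
        with pytest.raises(ValueError, match="overlap"):
            rdf(traj, [0, 1], [1], r_max=5.0, bin_width=0.5)


class TestDensityOverlap:
    def grid(self, values):
        values = np.asarray(values, dtype=float)
        return DensityGrid(GridSpec((0, 0, 0), 1.0, values.shape), values)

    def test_self_overlap_is_one(self, rng):
        g = self.grid(rng.uniform(0, 1, (3, 3, 3)))
        assert density_overlap(g, g) == 1.0

    def test_disjoint_is_zero(self):
        a = np.zeros((2, 2, 2))
        b = np.zeros((2, 2, 2))
        a[0, 0, 0] = 0.5
        b[1, 1, 1] = 0.5
        assert density_overlap(self.grid(a), self.grid(b)) == 0.0

    def test_constructed_half_overlap_is_one_third(self):
        # equal-valued boxes sharing half their occupied voxels:
        # sum(min)/sum(max) = 2 / 6 ... with 2 shared of 4 each -> 2/6 = 1/3
        a = np.zeros((4, 1, 1))
        b = np.zeros((4, 1, 1))
        a[[0, 1], 0, 0] = 0.8
        b[[1, 2], 0, 0] = 0.8
        a[3] = 0.0
        assert density_overlap(self.grid(a), self.grid(b)) == pytest.approx(1.0 / 3.0)

    def test_symmetry_and_voxel_permutation_invariance(self, rng):
        a = rng.uniform(0, 1, (3, 3, 3))
        b = rng.uniform(0, 1, (3, 3, 3))
        ga, gb = self.grid(a), self.grid(b)
        assert density_overlap(ga, gb) == pytest.approx(density_overlap(gb, ga))
        perm = rng.permutation(27)
        pa = self.grid(a.ravel()[perm].reshape(3, 3, 3))
        pb = self.grid(b.ravel()[perm].reshape(3, 3, 3))
        assert density_overlap(pa, pb) == pytest.approx(density_overlap(ga, gb))

    def test_incongruent_grids_rejected(self):
        a = self.grid(np.zeros((2, 2, 2)))
        b = DensityGrid(GridSpec((1, 0, 0), 1.0, (2, 2, 2)), np.zeros((2, 2, 2)))
        with pytest.raises(ValueError, match="congruent"):
            density_overlap(a, b)

    def test_empty_grids_identical(self):
        a = self.grid(np.zeros((2, 2, 2)))
        assert density_overlap(a, a) == 1.0


class TestOccupancyDensity:
    def test_static_atom_marks_one_voxel(self):
        topo = point_structure([[1.5, 1.5, 1.5]])
        traj = Trajectory(topo, topo.coords[None].repeat(8, axis=0))
        grid = occupancy_density(traj, [0], GridSpec((0, 0, 0), 1.0, (3, 3, 3)))
        assert grid.values[1, 1, 1] == 1.0
        assert grid.values.sum() == 1.0

    def test_out_of_grid_rejected(self):
        topo = point_structure([[10.0, 0, 0]])
        traj = Trajectory(topo, topo.coords[None])
        with pytest.raises(ValueError, match="outside"):
            occupancy_density(traj, [0], GridSpec((0, 0, 0), 1.0, (3, 3, 3)))

    def test_dx_export_parses(self, tmp_path):
        topo = point_structure([[0.5, 0.5, 0.5]])
        traj = Trajectory(topo, topo.coords[None])
        grid = occupancy_density(traj, [0], GridSpec((0, 0, 0), 1.0, (2, 2, 2)))
        path = tmp_path / "density.dx"
        grid.write_dx(path)
        text = path.read_text()
        assert "gridpositions counts 2 2 2" in text
        assert "items 8" in text
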