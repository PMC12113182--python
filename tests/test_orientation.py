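"""Grid tilt-angle maps and the below-45-degree orientation statistic."""

import numpy as np
import pytest

import poreramp as pr
from poreramp.orientation import GridAngleMap, local_normal
from conftest import surface_frame


def sin_slope(amplitude, Lx, x):
    return np.abs(amplitude * 2 * np.pi / Lx * np.cos(2 * np.pi * x / Lx))


class TestLocalNormal:
    def test_flat_plane(self):
        pts = np.array([[0, 0, 5.0], [1, 0, 5.0], [0, 1, 5.0], [1, 1, 5.0]])
        n = local_normal(pts)
        assert np.allclose(n, [0, 0, 1])

    def test_45_degree_incline(self):
        # plane z = x: normal (-1, 0, 1)/sqrt(2), oriented Z-positive
        pts = np.array([[0, 0, 0], [1, 0, 1], [0, 1, 0], [1, 1, 1.0]])
        n = local_normal(pts)
        assert n[2] > 0
        assert pr.angle_to_z(n) == pytest.approx(45.0, abs=1e-9)

    def test_noisy_plane_recovered_within_one_degree(self):
        rng = np.random.default_rng(0)
        xy = rng.uniform(0, 2, size=(50, 2))
        z = 0.3 * xy[:, 0] - 0.2 * xy[:, 1] + rng.normal(0, 0.005, 50)
        n = local_normal(np.column_stack([xy, z]))
        truth = np.array([-0.3, 0.2, 1.0])
        truth /= np.linalg.norm(truth)
        assert np.degrees(np.arccos(abs(np.dot(n, truth)))) < 1.0

    def test_degenerate_inputs_give_missing(self):
        assert local_normal(np.zeros((2, 3))) is None
        line = np.column_stack([np.arange(5.0), np.arange(5.0), np.zeros(5)])
        assert local_normal(line) is None


class TestAngleToZ:
    @pytest.mark.parametrize("vec, expected", [
        ((0, 0, 1), 0.0),
        ((1 / np.sqrt(2), 0, 1 / np.sqrt(2)), 45.0),
        ((1, 0, 0), 90.0),
    ])
    def test_reference_directions(self, vec, expected):
        assert pr.angle_to_z(np.array(vec)) == pytest.approx(expected, abs=1e-6)

    def test_non_unit_vector_rejected(self):
        with pytest.raises(ValueError, match="unit vector"):
            pr.angle_to_z(np.array([0.0, 0.0, 2.0]))


class TestComputeAngleMap:
    def test_flat_bilayer_is_all_zero(self, small_frame):
        amap = pr.compute_angle_map(small_frame, "upper")
        finite = amap.angles[np.isfinite(amap.angles)]
        assert finite.size > 0
        assert np.all(finite < 1.0)  # flat lattice up to jitter

    def test_sinusoid_matches_analytic_normals(self, default_system):
        A = 1.5
        frame = surface_frame(default_system, A)
        amap = pr.compute_angle_map(frame, "upper")
        Lx = default_system.box.Lx
        cx = (np.arange(amap.n_x) + 0.5) * (Lx / amap.n_x)
        analytic = np.degrees(np.arctan(sin_slope(A, Lx, cx)))
        measured = np.nanmean(amap.angles, axis=1)
        rms = np.sqrt(np.nanmean((measured - analytic) ** 2))
        assert rms < 2.0

    def test_sparse_quadrant_leaves_other_cells_missing(self, small_system):
        s = small_system.copy()
        pos = s.positions.copy()
        # collapse all lipids into one quadrant
        lip = s.lipid_bead_indices
        pos[lip, 0] = pos[lip, 0] % (s.box.Lx / 3)
        pos[lip, 1] = pos[lip, 1] % (s.box.Ly / 3)
        frame = pr.Frame(s, pos, 0.0)
        amap = pr.compute_angle_map(frame, "upper", halo=0.0)
        assert np.isnan(amap.angles).any()

    def test_empty_leaflet_raises(self, small_system):
        s = small_system.copy()
        s.leaflets[:] = "upper"
        frame = pr.Frame(s, s.positions, 0.0)
        with pytest.raises(Exception, match="lower"):
            pr.compute_angle_map(frame, "lower")


class TestFractionBelow:
    def test_flat_map_is_one(self, small_frame):
        amap = pr.compute_angle_map(small_frame, "upper")
        assert pr.fraction_below(amap) == 1.0

    def test_strict_inequality_at_the_threshold(self):
        angles = np.array([[10.0, 44.9], [45.0, 80.0]])
        amap = GridAngleMap(1.0, 2, 2, angles, "upper", 0.0)
        assert pr.fraction_below(amap, 45.0) == pytest.approx(0.5)

    def test_missing_cells_excluded_from_both_counts(self):
        angles = np.array([[10.0, np.nan], [np.nan, 80.0]])
        amap = GridAngleMap(1.0, 2, 2, angles, "upper", 0.0)
        assert pr.fraction_below(amap, 45.0) == pytest.approx(0.5)

    def test_all_missing_raises(self):
        amap = GridAngleMap(1.0, 1, 2, np.full((1, 2), np.nan), "upper", 0.0)
        with pytest.raises(ValueError, match="MISSING"):
            pr.fraction_below(amap)

    def test_sinusoid_fraction_matches_measure_of_set(self, default_system):
        # amplitude chosen so the analytic tilt crosses 45 deg on a known set
        A = 4.0
        frame = surface_frame(default_system, A)
        amap = pr.compute_angle_map(frame, "upper")
        Lx = default_system.box.Lx
        xs = np.linspace(0, Lx, 100001)
        frac_analytic = np.mean(np.degrees(np.arctan(sin_slope(A, Lx, xs))) < 45.0)
        frac = pr.fraction_below(amap)
        assert 0.0 < frac_analytic < 1.0
        assert abs(frac - frac_analytic) <= 1.0 / amap.n_x  # one cell column

    def test_decreases_with_undulation_amplitude(self, default_system):
        fracs = []
        for A in (0.5, 1.5, 2.5, 3.5, 4.5):
            amap = pr.compute_angle_map(surface_frame(default_system, A), "upper")
            fracs.append(pr.fraction_below(amap))
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))
        assert fracs[0] == 1.0 and fracs[-1] < 1.0


class TestEndpointOrientation:
    def _mini_traj(self, system, times):
        frames = [pr.Frame(system, system.positions.copy(), t) for t in times]
        return pr.Trajectory(topology=system, frames=frames)

    def test_exact_grid_hit_uses_that_frame(self, small_system):
        traj = self._mini_traj(small_system, [0.8, 0.9, 1.0, 1.1])
        proto = pr.FieldProtocol(0.16, 1.0)
        assert traj.frame_nearest(proto.rise_time).time == 1.0
        assert pr.endpoint_orientation(traj, proto) == 1.0

    def test_tie_breaks_toward_earlier_frame(self, small_system):
        traj = self._mini_traj(small_system, [0.9, 1.1])
        assert traj.frame_nearest(1.0).time == 0.9

    def test_short_trajectory_raises(self, small_system):
        traj = self._mini_traj(small_system, [0.0, 0.5])
        with pytest.raises(ValueError, match="rise phase"):
            pr.endpoint_orientation(traj, pr.FieldProtocol(0.16, 1.0))

    def test_fast_rise_keeps_higher_below_45_fraction(self):
        from conftest import SMALL_KW
        system = pr.build_system(seed=1, **SMALL_KW)

        def fracs(rise):
            out = []
            for seed in range(10):
                proto = pr.FieldProtocol(0.16, rise)
                traj, _, _ = pr.generate_trajectory(
                    system, proto, pr.SurrogateParams(seed=seed),
                    dt_out=0.25, record_forces=False)
                out.append(pr.endpoint_orientation(traj, proto))
            return np.array(out)

        assert fracs(1.0).mean() > fracs(30.0).mean()


class TestInvariances:
    def test_fraction_invariant_under_z_shift_and_quarter_turn(self, small_system):
        frame = surface_frame(small_system, 1.2)
        base = pr.fraction_below(pr.compute_angle_map(frame, "upper"))

        shifted = small_system.copy()
        shifted.positions = frame.positions.copy()
        shifted.positions[:, 2] = (shifted.positions[:, 2] + 3.7) % small_system.box.Lz
        shifted.leaflets[:] = "unassigned"
        f2 = pr.Frame(shifted, shifted.positions, 0.0)
        assert pr.fraction_below(pr.compute_angle_map(f2, "upper")) == \
            pytest.approx(base, abs=2 / small_system.box.Lx ** 2 * 4)

        rot = small_system.copy()
        p = frame.positions.copy()
        rot.positions = np.column_stack(
            [p[:, 1], (small_system.box.Lx - p[:, 0]) % small_system.box.Lx, p[:, 2]])
        f3 = pr.Frame(rot, rot.positions, 0.0)
        n_cells = pr.compute_angle_map(frame, "upper").angles.size
        frac3 = pr.fraction_below(pr.compute_angle_map(f3, "upper"))
        assert abs(frac3 - base) <= 1.5 / n_cells * n_cells ** 0.5  # ~1 cell row
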