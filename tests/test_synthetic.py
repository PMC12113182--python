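"""Surrogate generator: composition, dynamics, determinism and pore logic."""

import numpy as np
import pytest

import poreramp as pr
from poreramp.synthetic import Undulation, _equilibrium_amplitude
from conftest import SMALL_KW

TINY_KW = dict(n_lipids=32, n_cations=4, n_anions=4, n_waters=400,
               box=(3.2, 3.2, 12.5))


class TestBuildSystem:
    def test_default_composition(self, default_system):
        s = default_system
        assert s.n_lipids == 1024
        assert int((s.categories == 0).sum()) == 12288
        assert len(s.cation_indices) == 244 and len(s.anion_indices) == 244

    def test_minimal_two_lipid_system(self):
        s = pr.build_system(n_lipids=2, n_cations=0, n_anions=0, n_waters=0,
                            box=(2.0, 2.0, 12.5))
        assert s.n_beads == 24

    def test_same_seed_is_bit_identical(self):
        a = pr.build_system(seed=5, **TINY_KW)
        b = pr.build_system(seed=5, **TINY_KW)
        assert np.array_equal(a.positions, b.positions)

    def test_lattice_overflow_raises(self):
        with pytest.raises(ValueError, match="lattice overflow"):
            pr.build_system(n_lipids=128, n_cations=0, n_anions=0, n_waters=0,
                            box=(2.0, 2.0, 12.5), area_per_lipid=0.58)

    def test_odd_lipid_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            pr.build_system(n_lipids=3)

    def test_waters_stay_out_of_the_hydrophobic_slab(self, small_system):
        wz = small_system.positions[small_system.water_indices, 2]
        mid = small_system.box.Lz / 2
        assert np.all(np.abs(wz - mid) > 2.3)


class TestTiltRelaxation:
    def test_noise_free_step_field_relaxes_exponentially(self):
        """With noise off the posed surface amplitude follows the per-cell
        closed form theta_eq + (theta0 - theta_eq) * exp(-t / tau) exactly."""
        params = pr.SurrogateParams(seed=9, thermal_noise_sigma=0.0,
                                    deformation_amp=1e-12,
                                    force_noise_sigma=0.0,
                                    nucleation_rate0=1e-12)
        system = pr.build_system(seed=2, **TINY_KW)
        proto = pr.FieldProtocol(0.16, 0.0)  # field held at the peak from t=0
        dt = 0.1
        traj, _, _ = pr.generate_trajectory(system, proto, params, dt_out=dt,
                                            max_plateau=2.0)
        # independent replication of the generator's grid geometry
        rng = np.random.default_rng(params.seed)
        und = Undulation(system.box, params.undulation_modes, rng)
        box = system.box
        n_x, n_y = int(box.Lx // 1.0), int(box.Ly // 1.0)
        cx = (np.arange(n_x) + 0.5) * (box.Lx / n_x)
        cy = (np.arange(n_y) + 0.5) * (box.Ly / n_y)
        cell_xy = np.stack(np.meshgrid(cx, cy, indexing="ij"), -1).reshape(-1, 2)
        g = np.linalg.norm(und.gradient(cell_xy), axis=1)
        mean_g = np.mean(g)
        theta0 = np.degrees(np.arctan(params.undulation_amp0 * g))
        amp_eq = _equilibrium_amplitude(params, 0.16, 1.0)
        theta_eq = np.degrees(np.arctan(amp_eq * g))
        decay = np.exp(-dt / params.tilt_relax_tau)

        po4 = system.po4_indices()
        anchors = system.positions[po4, :2]
        u = und.height(anchors)
        for k in (0, 3, 8, 15):
            theta_k = theta_eq + (theta0 - theta_eq) * decay ** (k + 1)
            amp_pred = np.mean(np.tan(np.radians(np.clip(theta_k, 0, 80)))) / mean_g
            disp = traj.frames[k].positions[po4, 2] - system.positions[po4, 2]
            amp_obs = float(np.dot(disp, u) / np.dot(u, u))
            assert amp_obs == pytest.approx(amp_pred, rel=1e-9)

    def test_equilibrium_tilt_decreases_with_field_strength(self):
        """Stronger fields pull the local normals toward Z: at identical
        seeds with noise off, the long-time mean tilt at E2 > E1 is <=."""
        system = pr.build_system(seed=2, **TINY_KW)

        def final_amp(peak):
            params = pr.SurrogateParams(seed=9, thermal_noise_sigma=0.0,
                                        force_noise_sigma=0.0,
                                        nucleation_rate0=1e-12)
            traj, _, _ = pr.generate_trajectory(
                system, pr.FieldProtocol(peak, 0.0), params,
                dt_out=0.5, max_plateau=40.0)
            po4 = system.po4_indices()
            disp = traj.frames[-1].positions[po4, 2] - system.positions[po4, 2]
            return float(np.sqrt(np.mean(disp ** 2)))

        assert final_amp(0.20) <= final_amp(0.16) <= final_amp(0.05)


class TestPoreNucleation:
    def test_no_pore_without_field_when_hazard_is_negligible(self):
        """Hazard bound: with rate0 = 1e-8/ns and E = 0 the expected number
        of nucleations in 50 ns is < 5e-7, so 20 seeds must all stay intact."""
        params_base = dict(thermal_noise_sigma=0.0, force_noise_sigma=0.0,
                           nucleation_rate0=1e-8, tension_penalty=5.0)
        system = pr.build_system(seed=2, **TINY_KW)
        intact = 0
        for seed in range(20):
            params = pr.SurrogateParams(seed=seed, **params_base)
            traj, _, _ = pr.generate_trajectory(
                system, pr.FieldProtocol(1e-9, 0.0), params,
                dt_out=1.0, max_plateau=50.0, record_forces=False)
            intact += traj.metadata["pore_time"] is None
        assert intact >= 19

    def test_median_pore_time_shorter_for_fast_rise(self):
        system = pr.build_system(seed=1, **SMALL_KW)

        def pore_times(rise):
            out = []
            for seed in range(5):
                traj, _, _ = pr.generate_trajectory(
                    system, pr.FieldProtocol(0.16, rise),
                    pr.SurrogateParams(seed=seed), dt_out=0.25,
                    record_forces=False)
                out.append(traj.metadata["pore_time"])
            assert all(t is not None for t in out)
            return np.array(out, dtype=float)

        fast, slow = pore_times(1.0), pore_times(30.0)
        assert np.median(fast) < np.median(slow)
        assert fast.max() < slow.min()  # the orderings do not even overlap

    def test_one_pore_maximum_per_trajectory(self, small_system):
        traj, _, _ = pr.generate_trajectory(
            small_system, pr.FieldProtocol(0.20, 1.0),
            pr.SurrogateParams(seed=3), dt_out=0.25, record_forces=False)
        # pore frames carry exactly one pore patch
        event = pr.pore_formation_time(traj, pr.FieldProtocol(0.20, 1.0))
        assert event is not None
        assert all(r >= 0 for _, r in event.radius_series)

    def test_generation_is_bit_reproducible(self, small_system):
        kw = dict(dt_out=0.25, record_forces=True)
        proto = pr.FieldProtocol(0.16, 1.0)
        t1, p1, f1 = pr.generate_trajectory(small_system,
                                            proto, pr.SurrogateParams(seed=7), **kw)
        t2, p2, f2 = pr.generate_trajectory(small_system,
                                            proto, pr.SurrogateParams(seed=7), **kw)
        assert len(t1) == len(t2)
        for a, b in zip(t1.frames, t2.frames):
            assert np.array_equal(a.positions, b.positions)
            assert np.array_equal(a.forces, b.forces)
        assert np.array_equal(p1.Pxx, p2.Pxx)
        assert np.array_equal(f1["Fz"], f2["Fz"])


class TestPressureEmission:
    def test_pressure_series_encodes_tension_exactly(self, small_system):
        traj, press, _ = pr.generate_trajectory(
            small_system, pr.FieldProtocol(0.16, 1.0),
            pr.SurrogateParams(seed=2), dt_out=0.25, record_forces=False)
        _, gamma = pr.tension_series(press, smoothing_window=0.0)
        true = traj.metadata["gamma_true"]
        assert np.max(np.abs(gamma - true) / np.abs(true)) < 1e-9


class TestInjectPore:
    def test_injected_pore_is_detected(self, small_frame):
        f = pr.inject_pore(small_frame, (3.1, 3.1), 1.0)
        assert pr.detect_spanning_chain(f)

    def test_zero_radius_leaves_frame_unchanged(self, small_frame):
        f = pr.inject_pore(small_frame, (3.1, 3.1), 0.0)
        assert np.array_equal(f.positions, small_frame.positions)
        assert not pr.detect_spanning_chain(f)

    def test_gap_in_the_column_breaks_detection(self, small_frame):
        from conftest import brute_force_spanning
        f = pr.inject_pore(small_frame, (3.1, 3.1), 0.3)
        topo = f.topology
        slab = pr.hydrophobic_slab(f)
        mid = (slab[0] + slab[1]) / 2
        widx = topo.water_indices
        w = f.positions[widx]
        in_col = (np.hypot(w[:, 0] - 3.1, w[:, 1] - 3.1) < 0.5) & \
                 (np.abs(w[:, 2] - mid) < 0.45)
        assert in_col.any()
        pos = f.positions.copy()
        pos[widx[in_col], 2] = 0.1  # delete the mid-slab beads (move to bulk)
        broken = pr.Frame(topo, pos, 0.0)
        assert not pr.detect_spanning_chain(broken)
        assert not brute_force_spanning(pos[widx], topo.box, *slab, 0.6)

    def test_oversized_radius_raises(self, small_frame):
        with pytest.raises(ValueError, match="too large"):
            pr.inject_pore(small_frame, (3.1, 3.1), 4.0)
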