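"""Water-chain pore detection, timing conventions, size and recovery."""

import numpy as np
import pytest

import poreramp as pr
from poreramp.system_model import MembraneError
from conftest import SMALL_KW, brute_force_spanning, water_only_system


class TestHydrophobicSlab:
    def _frame_with_po4_planes(self, z_lower, z_upper):
        s = pr.build_system(n_lipids=8, n_cations=0, n_anions=0, n_waters=20,
                            box=(2.0, 2.0, 12.5), seed=0)
        pos = s.positions.copy()
        up = s.leaflets == "upper"
        pos[s.po4_indices()[up], 2] = z_upper
        pos[s.po4_indices()[~up], 2] = z_lower
        return pr.Frame(s, pos, 0.0)

    def test_margin_arithmetic(self):
        f = self._frame_with_po4_planes(4.0, 8.0)
        assert pr.hydrophobic_slab(f, margin=0.3) == pytest.approx((4.3, 7.7))
        assert pr.hydrophobic_slab(f, margin=0.0) == pytest.approx((4.0, 8.0))

    def test_inverted_slab_raises(self):
        f = self._frame_with_po4_planes(6.2, 6.3)
        with pytest.raises(MembraneError, match="slab inverted"):
            pr.hydrophobic_slab(f, margin=0.3)


class TestDetectSpanningChain:
    def test_intact_bilayer_has_no_chain(self, small_frame):
        assert not pr.detect_spanning_chain(small_frame)

    def test_injected_pore_is_a_positive_control(self, small_frame):
        assert pr.detect_spanning_chain(pr.inject_pore(small_frame, (2.0, 2.0), 0.8))

    def test_nonpositive_cutoff_rejected(self, small_frame):
        with pytest.raises(ValueError, match="cutoff"):
            pr.detect_spanning_chain(small_frame, cutoff=0.0)

    @pytest.mark.parametrize("n_cases", [300])
    def test_agrees_with_brute_force_oracle(self, n_cases):
        rng = np.random.default_rng(12345)
        hits = 0
        for _ in range(n_cases):
            box = pr.Box(rng.uniform(2, 4), rng.uniform(2, 4), 8.0)
            n = rng.integers(5, 51)
            pts = np.column_stack([
                rng.uniform(0, box.Lx, n),
                rng.uniform(0, box.Ly, n),
                rng.uniform(0.5, 6.5, n),
            ])
            z_low, z_high = rng.uniform(2.0, 2.6), rng.uniform(4.2, 4.8)
            cutoff = rng.uniform(0.4, 1.2)
            sys = water_only_system(pts, box)
            frame = pr.Frame(sys, pts, 0.0)
            got = pr.detect_spanning_chain(frame, cutoff=cutoff,
                                           slab=(z_low, z_high))
            want = brute_force_spanning(pts, box, z_low, z_high, cutoff)
            assert got == want
            hits += want
        assert 0 < hits < n_cases  # both outcomes exercised

    def test_invariant_under_periodic_xy_translation(self, small_frame):
        f = pr.inject_pore(small_frame, (0.2, 6.0), 0.9)  # pore at a box edge
        assert pr.detect_spanning_chain(f)
        for shift in ((3.1, 0.0), (0.0, 4.5), (5.9, 5.9)):
            s = f.topology.copy()
            pos = f.positions.copy()
            pos[:, 0] = (pos[:, 0] + shift[0]) % s.box.Lx
            pos[:, 1] = (pos[:, 1] + shift[1]) % s.box.Ly
            assert pr.detect_spanning_chain(pr.Frame(s, pos, 0.0))


class TestPoreFormationTime:
    def _flicker_traj(self, small_system, pattern, dt=0.1):
        frames = []
        for k, has_pore in enumerate(pattern):
            f = pr.Frame(small_system, small_system.positions.copy(), k * dt)
            if has_pore:
                f = pr.inject_pore(f, (3.1, 3.1), 0.8)
                f.time = k * dt
            frames.append(f)
        return pr.Trajectory(topology=small_system, frames=frames)

    def test_first_persistent_frame_sets_both_conventions(self, small_system):
        traj = self._flicker_traj(small_system, [0, 0, 0, 1, 1, 1, 1])
        proto = pr.FieldProtocol(0.16, 0.2)
        ev = pr.pore_formation_time(traj, proto, persistence_frames=3,
                                    with_radius=False)
        assert ev.formation_time_total == pytest.approx(0.3)
        assert ev.formation_time_post_peak == pytest.approx(0.1)
        assert ev.persisted

    def test_single_frame_flicker_is_rejected(self, small_system):
        traj = self._flicker_traj(small_system, [0, 1, 0, 0, 0, 0])
        ev = pr.pore_formation_time(traj, pr.FieldProtocol(0.16, 0.1),
                                    persistence_frames=3, with_radius=False)
        assert ev is None

    def test_lower_persistence_never_delays_the_call(self, small_system):
        traj = self._flicker_traj(small_system, [0, 1, 0, 1, 1, 1, 1])
        proto = pr.FieldProtocol(0.16, 0.1)
        t3 = pr.pore_formation_time(traj, proto, 3, with_radius=False)
        t1 = pr.pore_formation_time(traj, proto, 1, with_radius=False)
        assert t1.formation_time_total <= t3.formation_time_total

    def test_surrogate_rise_orderings_do_not_overlap(self):
        system = pr.build_system(seed=1, **SMALL_KW)

        def detected_times(rise):
            ts = []
            for seed in range(5):
                proto = pr.FieldProtocol(0.16, rise)
                traj, _, _ = pr.generate_trajectory(
                    system, proto, pr.SurrogateParams(seed=seed),
                    dt_out=0.25, record_forces=False)
                ev = pr.pore_formation_time(traj, proto, with_radius=False)
                assert ev is not None
                ts.append(ev.formation_time_total)
            return np.array(ts)

        fast, slow = detected_times(1.0), detected_times(30.0)
        assert fast.max() < slow.min()


class TestPoreRadius:
    def test_injected_radius_recovered_within_grid_tolerance(self, small_frame):
        f = pr.inject_pore(small_frame, (3.1, 3.1), 1.0)
        assert pr.pore_radius(f) == pytest.approx(1.0, abs=0.25)

    def test_monotone_in_injected_radius(self, small_frame):
        r1 = pr.pore_radius(pr.inject_pore(small_frame, (3.1, 3.1), 1.0))
        r2 = pr.pore_radius(pr.inject_pore(small_frame, (3.1, 3.1), 2.0))
        assert r2 > r1

    def test_no_pore_raises(self, small_frame):
        with pytest.raises(ValueError, match="no transmembrane pore"):
            pr.pore_radius(small_frame)

    def test_single_patch_per_pore_frame(self, small_frame):
        # a pore crossing the periodic seam still counts as one patch
        f = pr.inject_pore(small_frame, (0.1, 0.1), 1.0)
        assert pr.pore_radius(f) == pytest.approx(1.0, abs=0.3)


class TestDetectRecovery:
    def _run(self, growth, fall_delay, seed=3):
        system = pr.build_system(seed=1, **SMALL_KW)
        proto = pr.FieldProtocol(0.16, 1.0, fall_time=5.0)
        params = pr.SurrogateParams(seed=seed, pore_growth_rate=growth)
        traj, _, _ = pr.generate_trajectory(system, proto, params,
                                            dt_out=0.25, fall_delay=fall_delay,
                                            record_forces=False)
        return traj, traj.metadata["protocol"]

    def test_box_scale_pore_never_recovers(self):
        traj, proto = self._run(growth=1.0, fall_delay=4.0)
        assert proto.fall_onset is not None
        assert pr.detect_recovery(traj, proto) is False

    def test_small_pore_reseals_during_the_fall(self):
        traj, proto = self._run(growth=0.2, fall_delay=2.0)
        assert pr.detect_recovery(traj, proto) is True

    def test_protocol_without_fall_is_not_applicable(self, small_system):
        frames = [pr.Frame(small_system, small_system.positions, t) for t in (0.0, 1.0)]
        traj = pr.Trajectory(topology=small_system, frames=frames)
        with pytest.raises(ValueError, match="falling edge"):
            pr.detect_recovery(traj, pr.FieldProtocol(0.16, 1.0))
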