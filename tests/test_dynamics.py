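import math

import numpy as np
import pytest
from scipy import stats

from tfsearch import ModelConfig
from tfsearch.dynamics import (BOUND, COMPLEXED, FREE, ParticleState,
                               attempt_adsorption, attempt_desorption,
                               attempt_ist, check_tg_binding,
                               dissociate_complex, event_probability,
                               rms_step, step_bound_1d, step_free_3d,
                               sticking_probability)


class TestStepFree3D:
    def test_zero_diffusion_is_fixed_point(self, rng):
        s = ParticleState(position=np.array([0.1, 0.2, 0.3]))
        out = step_free_3d(s, 0.0, 1e-4, 0.75, rng)
        assert np.allclose(out.position, s.position)

    def test_per_axis_rms_displacement(self, rng):
        # default parameters give a 23.3 nm per-axis rms step
        assert rms_step(2.72, 1e-4) * 1e3 == pytest.approx(23.32, abs=0.01)
        s = ParticleState(position=np.zeros(3))
        d = np.array([step_free_3d(s, 2.72, 1e-4, 100.0, rng).position
                      for _ in range(20_000)])
        assert d.std(axis=0) == pytest.approx([rms_step(2.72, 1e-4)] * 3,
                                              rel=0.03)

    def test_ensemble_msd_matches_free_diffusion_law(self, rng):
        # far from the boundary, MSD after k steps is 6*D*k*dt
        D, dt, k, n = 2.72, 1e-4, 20, 10_000
        pos = np.zeros((n, 3))
        state = ParticleState()
        for i in range(n):
            s = ParticleState(position=np.zeros(3))
            for _ in range(k):
                s = step_free_3d(s, D, dt, 1e3, rng)
            pos[i] = s.position
        msd = (pos ** 2).sum(axis=1).mean()
        expected = 6 * D * k * dt
        se = (pos ** 2).sum(axis=1).std() / math.sqrt(n)
        assert abs(msd - expected) < 3 * se

    def test_stays_inside_nucleus(self, rng):
        s = ParticleState(position=np.array([0.74, 0.0, 0.0]))
        R = 0.75
        for _ in range(500):
            s = step_free_3d(s, 2.72, 1e-4, R, rng)
            assert np.linalg.norm(s.position) <= R + 1e-12

    def test_requires_free_mode(self, rng):
        with pytest.raises(ValueError):
            step_free_3d(ParticleState(mode=BOUND), 2.72, 1e-4, 0.75, rng)


class TestStepBound1D:
    def test_rms_step_matches_reference(self):
        # 2.3 nm rms on-DNA step at default D1 and dt
        assert rms_step(0.0262, 1e-4) * 1e3 == pytest.approx(2.29, abs=0.005)

    def test_zero_diffusion_fixed_point(self, small_geometry, rng):
        s = ParticleState(mode=BOUND, segment=0, u=0.1, v=0.001)
        out = step_bound_1d(s, small_geometry, 0.0, 1e-4, rng)
        assert (out.segment, out.u, out.v) == (0, 0.1, 0.001)

    def test_coordinates_stay_on_face(self, small_geometry, rng):
        L = small_geometry.segments[0].length_um()
        w = small_geometry.width_nm * 1e-3
        s = ParticleState(mode=BOUND, segment=0, u=0.0, v=0.0)
        for _ in range(2000):
            s = step_bound_1d(s, small_geometry, 0.0262, 1e-4, rng)
            assert 0.0 <= s.u <= L
            assert 0.0 <= s.v <= w


class TestAdsorption:
    def test_sticking_probability_linear_in_kon(self):
        # adsorption flux at kon = 10 is 5.88x the flux at kon = 1.7
        ratio = (sticking_probability(10.0, 2.72, 1e-4)
                 / sticking_probability(1.7, 2.72, 1e-4))
        assert ratio == pytest.approx(10.0 / 1.7)

    def test_negative_kon_raises(self):
        with pytest.raises(ValueError):
            sticking_probability(-1.0, 2.72, 1e-4)

    def test_kon_zero_face_is_reflective(self, small_geometry, rng):
        # a path straight through the DNA plane must never adsorb and must
        # come back on the approach side
        seg = small_geometry.segments[0]
        above = seg.origin + 0.15 * seg.axis + 0.005 * seg.normal
        below = seg.origin + 0.15 * seg.axis - 0.005 * seg.normal
        for _ in range(200):
            s = ParticleState(position=above.copy())
            out = attempt_adsorption(s, below, small_geometry, 0.0, 2.72,
                                     1e-4, rng)
            assert out.mode == FREE
            assert (out.position - seg.origin) @ seg.normal > 0

    def test_crossing_can_adsorb_at_high_kon(self, small_geometry, rng):
        seg = small_geometry.segments[0]
        above = seg.origin + 0.15 * seg.axis + 0.005 * seg.normal
        below = seg.origin + 0.15 * seg.axis - 0.005 * seg.normal
        hits = 0
        for _ in range(500):
            s = ParticleState(position=above.copy())
            out = attempt_adsorption(s, below, small_geometry, 50.0, 2.72,
                                     1e-4, rng)
            if out.mode == BOUND:
                hits += 1
                assert out.segment == 0
                assert 0.0 <= out.u <= seg.length_um()
        p = sticking_probability(50.0, 2.72, 1e-4)
        assert hits / 500 == pytest.approx(p, abs=3 * math.sqrt(p / 500))


class TestDesorption:
    def test_koff_zero_never_desorbs(self, small_geometry, rng):
        s = ParticleState(mode=BOUND, segment=0, u=0.1, v=0.001)
        for _ in range(1000):
            assert attempt_desorption(s, small_geometry, 0.0, 2.72, 1e-4,
                                      rng) is s

    def test_residence_time_exponential(self, small_geometry, rng):
        # mean bound residence 1/11.6 s; distribution is exponential
        koff, dt = 11.6, 1e-4
        n = 600
        times = []
        for _ in range(n):
            s = ParticleState(mode=BOUND, segment=0, u=0.1, v=0.001)
            steps = 0
            while s.mode == BOUND:
                steps += 1
                s = attempt_desorption(s, small_geometry, koff, 2.72, dt, rng)
            times.append(steps * dt)
        times = np.array(times)
        assert times.mean() == pytest.approx(1 / koff,
                                             rel=3 / math.sqrt(n) + 0.01)
        # KS against Exp(11.6) must not reject at alpha = 0.01
        d, pval = stats.kstest(times, "expon", args=(0, 1 / koff))
        assert pval > 0.01

    def test_desorbed_particle_leaves_surface(self, small_geometry, rng):
        s = ParticleState(mode=BOUND, segment=0, u=0.1, v=0.001, face=0)
        seg = small_geometry.segments[0]
        out = s
        while out.mode == BOUND:
            out = attempt_desorption(out, small_geometry, 500.0, 2.72, 1e-4,
                                     rng)
        assert (out.position - seg.origin) @ seg.normal >= 0.0


class TestIST:
    def test_no_neighbours_never_fires(self, small_geometry, rng):
        s = ParticleState(mode=BOUND, segment=0, u=0.1, v=0.001)
        for _ in range(1000):
            assert attempt_ist(s, small_geometry, 11.6, 1e-4, rng) is s

    def test_transfer_preserves_and_clamps_u(self, rng):
        from tfsearch import GeometryLayout, StackSpec, build_geometry
        config = ModelConfig(ist_graph_kind="chain")
        g = build_geometry(config, GeometryLayout(
            stacks=[StackSpec(n_segments=2, length_bp=[420, 100])]))
        s = ParticleState(mode=BOUND, segment=0, u=420 * 0.34e-3, v=0.001)
        moved = s
        while moved.segment == 0:
            moved = attempt_ist(moved, g, 1e4, 1e-4, rng)
        assert moved.segment == 1
        assert moved.u == pytest.approx(100 * 0.34e-3)  # clamped

    def test_waiting_time_matches_rate(self, stack_geometry, rng):
        rate, dt, n = 11.6, 1e-4, 5000
        s = ParticleState(mode=BOUND, segment=5, u=0.05, v=0.001)
        waits = []
        steps = 0
        for _ in range(n):
            steps += 1
            out = attempt_ist(s, stack_geometry, rate, dt, rng)
            if out is not s:
                waits.append(steps * dt)
                steps = 0
                s = ParticleState(mode=BOUND, segment=int(out.segment),
                                  u=out.u, v=out.v)
        waits = np.array(waits)
        assert waits.mean() == pytest.approx(
            1 / rate, rel=3 / math.sqrt(len(waits)) + 0.02)


class TestTgBinding:
    def test_distance_zero_binds(self, small_geometry):
        tg = small_geometry.tg_list[0]
        u = tg.position_bp * 0.34e-3
        s = ParticleState(mode=BOUND, segment=0, u=u,
                          v=0.5 * small_geometry.width_nm * 1e-3)
        occ = np.zeros(1, dtype=np.int64)
        out = check_tg_binding(s, small_geometry, 2.0, occ)
        assert out.mode == COMPLEXED and out.tg == 0 and occ[0] == 1

    def test_occupied_tg_rejected(self, small_geometry):
        tg = small_geometry.tg_list[0]
        s = ParticleState(mode=BOUND, segment=0, u=tg.position_bp * 0.34e-3,
                          v=0.0013)
        occ = np.ones(1, dtype=np.int64)
        assert check_tg_binding(s, small_geometry, 2.0, occ).mode == BOUND

    def test_out_of_radius_does_not_bind(self, small_geometry):
        tg = small_geometry.tg_list[0]
        s = ParticleState(mode=BOUND, segment=0,
                          u=tg.position_bp * 0.34e-3 + 0.005, v=0.0013)
        occ = np.zeros(1, dtype=np.int64)
        assert check_tg_binding(s, small_geometry, 2.0, occ).mode == BOUND

    def test_free_tf_binds_only_when_allowed(self, small_geometry):
        tg = small_geometry.tg_list[0]
        seg = small_geometry.segments[0]
        pos = seg.origin + tg.position_bp * 0.34e-3 * seg.axis
        occ = np.zeros(1, dtype=np.int64)
        s = ParticleState(mode=FREE, position=pos.copy())
        assert check_tg_binding(s, small_geometry, 2.0, occ).mode == FREE
        out = check_tg_binding(s, small_geometry, 2.0, occ,
                               allow_3d_tg_binding=True)
        assert out.mode == COMPLEXED

    def test_sliding_tf_rarely_steps_over_tg(self, small_geometry, rng):
        # the binding radius (2 nm) exceeds the 2.3 nm rms step enough that
        # a TF sliding across the TG is captured on nearly every pass
        tg_u = small_geometry.tg_list[0].position_bp * 0.34e-3
        captures = 0
        n = 300
        for _ in range(n):
            s = ParticleState(mode=BOUND, segment=0, u=tg_u - 0.01,
                              v=0.0013)
            occ = np.zeros(1, dtype=np.int64)
            for _ in range(100_000):
                s = step_bound_1d(s, small_geometry, 0.0262, 1e-4, rng)
                s = check_tg_binding(s, small_geometry, 2.0, occ)
                if s.mode == COMPLEXED:
                    captures += 1
                    break
                if s.u > tg_u + 0.01:  # walked past without binding
                    break
        assert captures / n > 0.9


class TestComplexDissociation:
    def test_zero_rate_is_permanent(self, small_geometry, rng):
        s = ParticleState(mode=COMPLEXED, tg=0)
        occ = np.ones(1, dtype=np.int64)
        for _ in range(1000):
            assert dissociate_complex(s, small_geometry, 0.0, 2.72, 1e-4,
                                      occ, rng) is s

    def test_release_decrements_occupancy(self, small_geometry, rng):
        s = ParticleState(mode=COMPLEXED, tg=0)
        occ = np.ones(1, dtype=np.int64)
        out = s
        while out.mode == COMPLEXED:
            out = dissociate_complex(out, small_geometry, 100.0, 2.72, 1e-4,
                                     occ, rng)
        assert occ[0] == 0
        assert out.mode == FREE
        assert np.linalg.norm(out.position) <= small_geometry.nucleus_radius
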