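import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tfsearch import (GeometryLayout, ModelConfig, Placement, StackSpec,
                      build_geometry, run_replicates, run_simulation)


class TestRunSimulation:
    def test_zero_tfs_empty_log(self, default_config, small_geometry):
        log = run_simulation(default_config, small_geometry,
                             Placement.random_free(0), seed=1, t_end=0.1)
        assert log.n_events() == 0
        assert (log.counts["complexes"] == 0).all()

    def test_same_seed_identical_logs(self, small_geometry):
        config = ModelConfig(t_end=2.0)
        logs = [run_simulation(config, small_geometry,
                               Placement.random_free(10), seed=7)
                for _ in range(2)]
        pd.testing.assert_frame_equal(logs[0].events, logs[1].events)
        pd.testing.assert_frame_equal(logs[0].counts, logs[1].counts)

    def test_different_seed_different_logs(self, small_geometry):
        # start everyone bound so the desorption traffic differs by seed
        config = ModelConfig(t_end=2.0, kon=20.0)
        placement = Placement.bound([(0, 100.0 * (i + 1)) for i in range(8)])
        a = run_simulation(config, small_geometry, placement, seed=7)
        b = run_simulation(config, small_geometry, placement, seed=8)
        assert a.n_events() > 0
        assert not a.events.equals(b.events)

    def test_event_times_non_decreasing(self, small_geometry):
        config = ModelConfig(t_end=5.0)
        log = run_simulation(config, small_geometry,
                             Placement.random_free(20), seed=3)
        assert (np.diff(log.events["time"]) >= 0).all()

    def test_all_rates_zero_is_fixed_point(self, small_geometry):
        config = ModelConfig(D3=0.0, D1=0.0, kon=0.0, koff=0.0, ist_rate=0.0,
                             k_complex_off=0.0, t_end=1.0)
        log = run_simulation(config, small_geometry,
                             Placement.bound([(0, 100.0)]), seed=1)
        assert log.n_events() == 0
        assert log.final_mode[0] == 1  # still bound where it started

    def test_non_finite_parameter_rejected(self, small_geometry):
        config = ModelConfig(t_end=1.0)
        config.D3 = math.inf  # bypasses __post_init__
        with pytest.raises(ValueError):
            run_simulation(config, small_geometry, Placement.random_free(1),
                           seed=1)

    def test_overflow_retry_is_deterministic(self, small_geometry):
        config = ModelConfig(koff=50.0, t_end=2.0)
        small = run_simulation(config, small_geometry,
                               Placement.random_free(20), seed=5,
                               event_capacity=200)
        big = run_simulation(config, small_geometry,
                             Placement.random_free(20), seed=5,
                             event_capacity=1_000_000)
        pd.testing.assert_frame_equal(small.events, big.events)

    def test_tf_count_conserved(self, small_geometry):
        config = ModelConfig(t_end=5.0, k_complex_off=0.025)
        log = run_simulation(config, small_geometry,
                             Placement.random_free(25), seed=2)
        assert len(log.final_mode) == 25
        assert set(np.unique(log.final_mode)) <= {0, 1, 2}

    def test_complex_count_series_consistent_with_events(self, small_geometry):
        config = ModelConfig(t_end=60.0, k_complex_off=0.025)
        log = run_simulation(config, small_geometry,
                             Placement.random_free(30), seed=11,
                             sample_interval=1.0)
        ev = log.events
        sel = ev[ev["kind"].isin(["tg_bind", "tg_unbind"])]
        t = sel["time"].to_numpy()
        delta = np.where(sel["kind"].to_numpy() == "tg_bind", 1, -1)
        for _, row in log.counts.iterrows():
            expected = int(delta[t <= row["time"]].sum())
            assert expected == int(row["complexes"])

    def test_complex_lifetime_exponential(self, small_geometry):
        # 200 TFs start complexed with no possibility of rebinding; the
        # unbinding times follow Exp(0.025): mean 40 s, half-life 27.7 s
        config = ModelConfig(D3=0.0, kon=0.0, k_complex_off=0.025,
                             t_end=400.0)
        layout = GeometryLayout(
            stacks=[StackSpec(n_segments=1, length_bp=1000)],
            tg=[(0, 500.0)])
        layout_geom = build_geometry(config, layout)
        config2 = config.replace(allow_multiple_tf_per_tg=True)
        log = run_simulation(config2, layout_geom,
                             Placement.complexed([0] * 200), seed=4)
        times = log.events.loc[log.events["kind"] == "tg_unbind",
                               "time"].to_numpy()
        assert len(times) > 180
        assert times.mean() == pytest.approx(
            40.0, rel=3 / math.sqrt(len(times)) + 0.02)
        d, pval = stats.kstest(times, "expon", args=(0, 40.0))
        assert pval > 0.01


class TestRunReplicates:
    def test_n_below_one_raises(self, default_config, small_geometry):
        with pytest.raises(ValueError):
            run_replicates(default_config, small_geometry,
                           Placement.random_free(1), 0, base_seed=0)

    def test_single_replicate_zero_sd(self, small_geometry):
        config = ModelConfig(t_end=1.0)
        summary = run_replicates(config, small_geometry,
                                 Placement.random_free(5), 1, base_seed=0)
        assert summary.n == 1
        assert summary.sd_steady_state == 0.0 or math.isnan(
            summary.sd_steady_state)

    def test_identical_base_seed_identical_summary(self, small_geometry):
        config = ModelConfig(t_end=2.0)
        a = run_replicates(config, small_geometry, Placement.random_free(5),
                           3, base_seed=9)
        b = run_replicates(config, small_geometry, Placement.random_free(5),
                           3, base_seed=9)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_censoring_reported(self, small_geometry):
        # kon = 0 and no 3D binding: nothing can ever bind
        config = ModelConfig(kon=0.0, t_end=1.0)
        summary = run_replicates(config, small_geometry,
                                 Placement.random_free(3), 4, base_seed=0)
        assert summary.n_censored == 4
        assert math.isnan(summary.mean_first_binding_time)


class TestPlacement:
    def test_bound_placement_validates_range(self, small_geometry,
                                             default_config):
        with pytest.raises(ValueError):
            run_simulation(default_config, small_geometry,
                           Placement.bound([(0, 5000.0)]), seed=1, t_end=0.01)

    def test_free_at_outside_nucleus_raises(self, small_geometry,
                                            default_config):
        with pytest.raises(ValueError):
            run_simulation(default_config, small_geometry,
                           Placement.free_at([(0.9, 0.0, 0.0)]), seed=1,
                           t_end=0.01)

    def test_unknown_tg_raises(self, small_geometry, default_config):
        with pytest.raises(ValueError):
            run_simulation(default_config, small_geometry,
                           Placement.complexed([5]), seed=1, t_end=0.01)
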