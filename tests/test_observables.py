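import math

import numpy as np
import pandas as pd
import pytest

from tfsearch import DistanceResponse, ModelConfig, Placement, run_simulation
from tfsearch.engine import EventLog
from tfsearch.observables import (first_binding_time, half_max_time,
                                  loglog_slope, recovery_curve,
                                  saturation_length, steady_state_count)


def make_log(events=None, counts=None, n_tf=10, t_end=100.0):
    if events is None:
        events = pd.DataFrame(columns=["time", "tf", "kind", "where", "u_bp"])
    if counts is None:
        counts = pd.DataFrame({"time": [0.0, t_end], "complexes": [0, 0]})
    return EventLog(events=events, counts=counts,
                    meta={"seed": 0, "n_tf": n_tf, "t_end": t_end,
                          "config_hash": "x", "dt": 1e-4,
                          "n_steps": int(t_end / 1e-4),
                          "stopped_early": False, "placement": "test"})


def bind_events(specs):
    return pd.DataFrame([
        {"time": t, "tf": tf, "kind": kind, "where": 0, "u_bp": np.nan}
        for t, tf, kind in specs])


class TestFirstBindingTime:
    def test_no_binding_is_censored(self):
        assert math.isnan(first_binding_time(make_log()))

    def test_earliest_event_wins(self):
        log = make_log(bind_events([(12.5, 0, "tg_bind"),
                                    (80.0, 1, "tg_bind")]))
        assert first_binding_time(log) == 12.5


class TestHalfMaxTime:
    def test_reaches_half_of_steady_state(self):
        ev = bind_events([(10.0 * (i + 1), i, "tg_bind") for i in range(10)])
        log = make_log(ev)
        # steady state 10 -> target ceil(5) reached at the 5th event (t=50)
        assert half_max_time(log, 10) == 50.0

    def test_ceiling_for_odd_counts(self):
        ev = bind_events([(5.0, 0, "tg_bind"), (9.0, 1, "tg_bind")])
        assert half_max_time(make_log(ev), 3) == 9.0  # ceil(1.5) = 2

    def test_steady_state_one_equals_first_binding(self):
        ev = bind_events([(12.5, 0, "tg_bind")])
        log = make_log(ev)
        assert half_max_time(log, 1) == first_binding_time(log)

    def test_never_reached_is_censored(self):
        ev = bind_events([(5.0, 0, "tg_bind")])
        assert math.isnan(half_max_time(make_log(ev), 10))

    def test_not_after_steady_state_for_monotone_counts(self):
        ev = bind_events([(float(t), t, "tg_bind") for t in range(1, 9)])
        log = make_log(ev)
        assert half_max_time(log, 8) <= 8.0

    def test_non_positive_steady_state_raises(self):
        with pytest.raises(ValueError):
            half_max_time(make_log(), 0)


class TestSteadyStateCount:
    def test_time_average_of_tail(self):
        counts = pd.DataFrame({"time": np.arange(0.0, 101.0, 1.0),
                               "complexes": [0] * 91 + [7] * 10})
        log = make_log(counts=counts, t_end=100.0)
        assert steady_state_count(log) == pytest.approx(7.0, abs=0.7)


class TestRecoveryCurve:
    def test_starts_at_zero_and_is_monotone(self):
        ev = bind_events([(3.0, 0, "tg_unbind"), (9.0, 1, "tg_unbind")])
        curve = recovery_curve(make_log(ev, n_tf=4))
        assert curve["fraction"].iloc[0] == 0.0
        assert (np.diff(curve["fraction"]) >= 0).all()
        assert (curve["fraction"] <= 1.0).all()
        assert curve["fraction"].iloc[-1] == pytest.approx(0.5)

    def test_matches_exponential_unbinding(self, small_geometry):
        # no rebinding: fraction recovered = 1 - exp(-0.025 t), half at 27.7 s
        config = ModelConfig(D3=0.0, kon=0.0, k_complex_off=0.025,
                             t_end=200.0, allow_multiple_tf_per_tg=True)
        log = run_simulation(config, small_geometry,
                             Placement.complexed([0] * 300), seed=8)
        curve = recovery_curve(log)
        t_half = math.log(2) / 0.025
        frac_at_half = curve.loc[curve["time"] <= t_half, "fraction"].iloc[-1]
        assert frac_at_half == pytest.approx(0.5, abs=3 * 0.5 / math.sqrt(300))


class TestLogLogSlope:
    def test_quadratic_gives_two(self):
        d = np.array([1.0, 2.0, 4.0, 8.0])
        slope, ci = loglog_slope(d, d ** 2)
        assert slope == pytest.approx(2.0, abs=1e-12)

    def test_constant_gives_zero(self):
        slope, _ = loglog_slope([1, 2, 4, 8], [5.0] * 4)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            loglog_slope([1, 2], [1, 2])

    def test_non_positive_means_raise(self):
        with pytest.raises(ValueError):
            loglog_slope([1, 2, 3], [1.0, -2.0, 3.0])


class TestSaturationLength:
    def test_exponential_saturation_knee(self):
        L = np.arange(25, 2001, 25.0)
        m = 1.0 - np.exp(-L / 200.0)
        knee = saturation_length(L, m)
        # 1 - 1/e of the plateau is reached near the length constant
        assert knee == pytest.approx(200.0, rel=0.05)


class TestDistanceResponse:
    def test_from_samples_handles_censoring(self):
        dr = DistanceResponse.from_samples({
            100.0: np.array([1.0, 2.0, math.nan]),
            200.0: np.array([3.0, 5.0, 4.0]),
            400.0: np.array([8.0, 9.0, 10.0]),
        })
        assert list(dr.table["n_censored"]) == [1, 0, 0]
        slope, _ = dr.slope()
        assert slope > 0

    def test_distances_must_increase(self):
        with pytest.raises(ValueError):
            DistanceResponse(table=pd.DataFrame(
                {"distance_bp": [2.0, 1.0, 3.0], "mean": [1, 1, 1],
                 "sd": [0, 0, 0], "n": [1, 1, 1], "n_censored": [0, 0, 0]}))
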