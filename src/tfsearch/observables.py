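"""Statistics computed from event logs.

All observables are pure functions of an :class:`~tfsearch.engine.EventLog`
(or of plain arrays) and can be recomputed at any time.  Censored values are
represented as NaN and excluded from means; callers receive censoring counts
alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .engine import EventLog

__all__ = [
    "first_binding_time", "half_max_time", "steady_state_count",
    "recovery_curve", "loglog_slope", "saturation_length",
    "DistanceResponse",
]


def first_binding_time(log: EventLog) -> float:
    """Time of the first specific (TF–TG) binding event; NaN if the run
    ended without one (censored)."""
    ev = log.events
    bind = ev.loc[ev["kind"] == "tg_bind", "time"]
    if len(bind) == 0:
        return math.nan
    return float(bind.iloc[0])


def _count_series_from_events(log: EventLog) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct the exact complex-count step function from bind/unbind
    events (starting from the initial sampled count)."""
    ev = log.events
    sel = ev["kind"].isin(["tg_bind", "tg_unbind"])
    t = ev.loc[sel, "time"].to_numpy()
    delta = np.where(ev.loc[sel, "kind"].to_numpy() == "tg_bind", 1, -1)
    c0 = int(log.counts["complexes"].iloc[0]) if len(log.counts) else 0
    return t, c0 + np.cumsum(delta)


def half_max_time(log: EventLog, steady_state: float) -> float:
    """First time the complex count reaches ⌈steady_state / 2⌉; NaN if that
    level is never reached (censored)."""
    if steady_state <= 0:
        raise ValueError("steady_state must be > 0")
    target = math.ceil(steady_state / 2.0)
    t, c = _count_series_from_events(log)
    if len(t):
        hit = np.nonzero(c >= target)[0]
        if len(hit):
            return float(t[hit[0]])
        return math.nan
    # fall back to the sampled series when bind events were not recorded
    counts = log.counts
    hit = counts.index[counts["complexes"] >= target]
    if len(hit):
        return float(counts.loc[hit[0], "time"])
    return math.nan


def steady_state_count(log: EventLog, final_fraction: float = 0.1) -> float:
    """Steady-state complex count, estimated as the time average of the
    sampled complex-count series over the final ``final_fraction`` of the
    run."""
    counts = log.counts
    if len(counts) == 0:
        return 0.0
    t_end = log.meta["t_end"]
    t0 = t_end * (1.0 - final_fraction)
    tail = counts[counts["time"] >= t0]
    if len(tail) == 0:
        tail = counts.tail(1)
    return float(tail["complexes"].mean())


def recovery_curve(log: EventLog, normalisation: int | None = None) -> pd.DataFrame:
    """Fraction of the initially complexed TFs that have unbound by time t
    (FRAP-style recovery), as a non-decreasing step series in [0, 1].

    ``normalisation`` defaults to the number of TFs in the run (all assumed
    to start complexed).
    """
    n0 = log.meta["n_tf"] if normalisation is None else normalisation
    if n0 <= 0:
        raise ValueError("normalisation must be > 0")
    ev = log.events
    # first unbinding time of each TF that started complexed
    unb = ev[ev["kind"] == "tg_unbind"].drop_duplicates(subset="tf")
    t = np.concatenate([[0.0], np.sort(unb["time"].to_numpy())])
    frac = np.arange(0, len(t)) / n0
    return pd.DataFrame({"time": t, "fraction": np.minimum(frac, 1.0)})


def loglog_slope(distances, means, confidence: float = 0.95):
    """Least-squares slope of log(mean) vs log(distance) with a confidence
    interval.  Requires ≥ 3 finite, positive points."""
    d = np.asarray(distances, dtype=float)
    m = np.asarray(means, dtype=float)
    ok = np.isfinite(d) & np.isfinite(m)
    d, m = d[ok], m[ok]
    if len(d) < 3:
        raise ValueError("need at least 3 finite points")
    if np.any(d <= 0) or np.any(m <= 0):
        raise ValueError("distances and means must be positive")
    res = stats.linregress(np.log(d), np.log(m))
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, len(d) - 2)
    return float(res.slope), (float(res.slope - tcrit * res.stderr),
                              float(res.slope + tcrit * res.stderr))


def saturation_length(lengths, means, level: float = 1.0 - math.exp(-1.0)) -> float:
    """Length at which a rising-then-saturating response first reaches
    ``level`` × its plateau (linear interpolation).  The plateau is the mean
    of the two largest-length values."""
    L = np.asarray(lengths, dtype=float)
    m = np.asarray(means, dtype=float)
    order = np.argsort(L)
    L, m = L[order], m[order]
    if len(L) < 3:
        raise ValueError("need at least 3 points")
    plateau = m[-2:].mean()
    target = level * plateau
    for i in range(len(L)):
        if m[i] >= target:
            if i == 0:
                return float(L[0])
            f = (target - m[i - 1]) / (m[i] - m[i - 1])
            return float(L[i - 1] + f * (L[i] - L[i - 1]))
    return float(L[-1])


@dataclass
class DistanceResponse:
    """Mean (± SD) of a statistic as a function of start distance."""

    table: pd.DataFrame  # columns: distance_bp, mean, sd, n, n_censored

    def __post_init__(self):
        d = self.table["distance_bp"].to_numpy()
        if not np.all(np.diff(d) > 0):
            raise ValueError("distances must be strictly increasing")
        if (self.table["n"] < 1).any():
            raise ValueError("each point needs n >= 1")

    def slope(self, confidence: float = 0.95):
        """Fitted log–log slope of mean vs distance, with CI."""
        return loglog_slope(self.table["distance_bp"], self.table["mean"],
                            confidence)

    @classmethod
    def from_samples(cls, samples: dict[float, np.ndarray]) -> "DistanceResponse":
        """Build from {distance_bp: array of per-replicate values (NaN =
        censored)}."""
        rows = []
        for d in sorted(samples):
            x = np.asarray(samples[d], dtype=float)
            ok = np.isfinite(x)
            rows.append(dict(
                distance_bp=d,
                mean=float(x[ok].mean()) if ok.any() else math.nan,
                sd=float(x[ok].std(ddof=1)) if ok.sum() > 1 else 0.0,
                n=int(ok.sum()),
                n_censored=int((~ok).sum()),
            ))
        return cls(table=pd.DataFrame(rows))
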