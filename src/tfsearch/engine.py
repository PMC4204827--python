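"""Time-stepping engine: whole-simulation runs, replicates, event logs.

A run is fully determined by (config, geometry, placement, seed): the same
seed produces bit-identical event logs.  Replicate seeds are derived as
``base_seed + i``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernel as K
from .config import ModelConfig
from .dynamics import event_probability, sticking_probability
from .geometry import Geometry, bp_to_nm

__all__ = [
    "Placement", "EventLog", "ReplicateSummary",
    "run_simulation", "run_replicates",
]

EVENT_NAMES = ["adsorb", "desorb", "ist", "tg_bind", "tg_unbind"]
_EVENT_CODE = {name: i for i, name in enumerate(EVENT_NAMES)}


@dataclass
class Placement:
    """Initial TF placement, resolved against the run's own RNG.

    Use the factory methods: :meth:`random_free`, :meth:`bound`,
    :meth:`free_at`, :meth:`complexed`.
    """

    kind: str
    n: int = 0
    entries: list = field(default_factory=list)

    @classmethod
    def random_free(cls, n: int) -> "Placement":
        """n TFs at uniformly random positions in the nuclear volume."""
        return cls(kind="random_free", n=int(n))

    @classmethod
    def bound(cls, entries: Sequence[tuple]) -> "Placement":
        """TFs starting non-specifically bound.  Each entry is
        (segment, u_bp) or (segment, u_bp, v_frac, face)."""
        return cls(kind="bound", n=len(entries), entries=list(entries))

    @classmethod
    def free_at(cls, points: Sequence[Sequence[float]]) -> "Placement":
        """TFs starting free at explicit 3D positions (µm)."""
        return cls(kind="free_at", n=len(points),
                   entries=[tuple(p) for p in points])

    @classmethod
    def complexed(cls, tg_ids: Sequence[int]) -> "Placement":
        """TFs starting already complexed to the given TGs."""
        return cls(kind="complexed", n=len(tg_ids), entries=list(tg_ids))

    def resolve(self, config: ModelConfig, geometry: Geometry,
                rng: np.random.Generator):
        n = self.n
        mode = np.zeros(n, dtype=np.int8)
        pos = np.zeros((n, 3))
        seg = np.full(n, -1, dtype=np.int64)
        uu = np.zeros(n)
        vv = np.zeros(n)
        face = np.zeros(n, dtype=np.int8)
        tgid = np.full(n, -1, dtype=np.int64)
        ntg = len(geometry.tg_list)
        tg_count = np.zeros(max(ntg, 1), dtype=np.int64)
        R = geometry.nucleus_radius
        w_um = geometry.width_nm * 1e-3
        if self.kind == "random_free":
            for i in range(n):
                while True:
                    p = (2.0 * rng.random(3) - 1.0) * R
                    if p @ p <= R * R:
                        break
                pos[i] = p
        elif self.kind == "free_at":
            for i, p in enumerate(self.entries):
                pos[i] = p
                if np.linalg.norm(pos[i]) > R:
                    raise ValueError(f"TF {i} placed outside the nucleus")
        elif self.kind == "bound":
            for i, e in enumerate(self.entries):
                s, u_bp = e[0], e[1]
                v_frac = e[2] if len(e) > 2 else 0.5
                fc = e[3] if len(e) > 3 else 0
                L_bp = geometry.segments[s].length_bp
                if not 0 <= u_bp <= L_bp:
                    raise ValueError(
                        f"TF {i}: u = {u_bp} bp outside segment of {L_bp} bp")
                mode[i] = K.MODE_BOUND
                seg[i] = s
                uu[i] = bp_to_nm(u_bp, geometry.rise_per_bp) * 1e-3
                vv[i] = v_frac * w_um
                face[i] = fc
        elif self.kind == "complexed":
            for i, t in enumerate(self.entries):
                if not 0 <= t < ntg:
                    raise ValueError(f"TF {i}: unknown TG {t}")
                mode[i] = K.MODE_COMPLEXED
                tgid[i] = t
                tg_count[t] += 1
        else:
            raise ValueError(f"unknown placement kind {self.kind!r}")
        return mode, pos, seg, uu, vv, face, tgid, tg_count


@dataclass
class EventLog:
    """Timestamped events plus the complex-count time series of one run."""

    events: pd.DataFrame  # columns: time, tf, kind, where, u_bp
    counts: pd.DataFrame  # columns: time, complexes
    meta: dict
    final_mode: np.ndarray = None
    final_tg_count: np.ndarray = None

    @property
    def seed(self) -> int:
        return self.meta["seed"]

    def n_events(self, kind: str | None = None) -> int:
        if kind is None:
            return len(self.events)
        return int((self.events["kind"] == kind).sum())


def _auto_capacity(config: ModelConfig, n_tf: int, nsteps: int,
                   record: tuple) -> int:
    dur = nsteps * config.dt
    est = 10_000
    if "adsorb" in record or "desorb" in record or "ist" in record:
        # generous upper estimate of non-specific event traffic
        est += int(4.0 * n_tf * dur * max(config.koff, config.ist_rate, 1.0))
    return min(est, 40_000_000)


def run_simulation(config: ModelConfig, geometry: Geometry,
                   placement: Placement, seed: int | None = None, *,
                   record: tuple = ("adsorb", "desorb", "ist", "tg_bind",
                                    "tg_unbind"),
                   sample_interval: float | None = None,
                   stop_after_bindings: int = 0,
                   non_depleting: bool = False,
                   t_end: float | None = None,
                   event_capacity: int | None = None) -> EventLog:
    """Advance all TFs from t = 0 to ``t_end`` (or until the stop condition).

    Parameters beyond the physical model: ``record`` selects which event
    kinds are logged; ``sample_interval`` (s) sets the complex-count
    sampling cadence (default ~2000 points per run);
    ``stop_after_bindings`` > 0 stops the run once that many specific
    binding events occurred (finding-time runs); ``non_depleting`` resets a
    TF to a random free position after each recorded binding instead of
    forming a complex (hazard estimation).
    """
    config.validate()
    for name in ("D3", "D1", "kon", "koff", "ist_rate", "k_complex_off",
                 "dt", "sigma_b"):
        if not math.isfinite(getattr(config, name)):
            raise ValueError(f"non-finite config parameter {name}")
    if seed is None:
        seed = config.seed
    dur = config.t_end if t_end is None else t_end
    nsteps = int(round(dur / config.dt))
    n_tf = placement.n
    geo = geometry.arrays()
    rec = np.zeros(5, dtype=np.uint8)
    for name in record:
        rec[_EVENT_CODE[name]] = 1
    if sample_interval is None:
        sample_every = max(1, nsteps // 2000)
    else:
        sample_every = max(1, int(round(sample_interval / config.dt)))
    nsamp_max = nsteps // sample_every + 2
    cap = event_capacity or _auto_capacity(config, n_tf, nsteps, record)
    pstick = sticking_probability(config.kon, config.D3, config.dt)
    p_desorb = event_probability(config.koff, config.dt)
    p_ist = event_probability(config.ist_rate, config.dt)
    p_coff = event_probability(config.k_complex_off, config.dt)
    tg_cap = (1 << 30) if config.allow_multiple_tf_per_tg else 1
    while True:
        rng = np.random.default_rng(seed)
        m0, p0, s0, u0, v0, f0, t0, tc0 = placement.resolve(
            config, geometry, rng)
        ev_t = np.zeros(cap)
        ev_tf = np.zeros(cap, dtype=np.int64)
        ev_kind = np.zeros(cap, dtype=np.int8)
        ev_a = np.zeros(cap, dtype=np.int64)
        ev_u = np.zeros(cap)
        samp_t = np.zeros(nsamp_max)
        samp_c = np.zeros(nsamp_max, dtype=np.int64)
        nev, nsamp, steps_done, status = K.advance(
            geo,
            config.D3, config.effective_D1, pstick, p_desorb, p_ist, p_coff,
            config.sigma_b_um, config.dt, nsteps,
            config.allow_3d_tg_binding, tg_cap, config.ist_randomize_u,
            non_depleting, stop_after_bindings,
            m0, p0, s0, u0, v0, f0, t0, tc0,
            ev_t, ev_tf, ev_kind, ev_a, ev_u, rec,
            sample_every, samp_t, samp_c,
            rng)
        if status != K.STATUS_OVERFLOW:
            break
        cap *= 4
    kinds = pd.Categorical.from_codes(ev_kind[:nev], categories=EVENT_NAMES)
    rise_um = geometry.rise_per_bp * 1e-3
    events = pd.DataFrame({
        "time": ev_t[:nev],
        "tf": ev_tf[:nev],
        "kind": kinds,
        "where": ev_a[:nev],
        "u_bp": np.where(ev_u[:nev] >= 0, ev_u[:nev] / rise_um, np.nan),
    })
    counts = pd.DataFrame({"time": samp_t[:nsamp],
                           "complexes": samp_c[:nsamp]})
    meta = {
        "seed": int(seed),
        "config_hash": config.hash(),
        "n_tf": n_tf,
        "dt": config.dt,
        "t_end": steps_done * config.dt,
        "n_steps": int(steps_done),
        "stopped_early": status == K.STATUS_STOPPED,
        "placement": placement.kind,
    }
    return EventLog(events=events, counts=counts, meta=meta,
                    final_mode=m0, final_tg_count=tc0[: max(1, len(
                        geometry.tg_list))])


@dataclass
class ReplicateSummary:
    """Across-replicate statistics of a repeated simulation."""

    table: pd.DataFrame  # one row per replicate
    n: int
    base_seed: int

    def _agg(self, col: str) -> tuple[float, float]:
        x = self.table[col].dropna()
        if len(x) == 0:
            return math.nan, math.nan
        return float(x.mean()), float(x.std(ddof=1)) if len(x) > 1 else 0.0

    @property
    def mean_first_binding_time(self) -> float:
        return self._agg("first_binding_time")[0]

    @property
    def sd_first_binding_time(self) -> float:
        return self._agg("first_binding_time")[1]

    @property
    def mean_steady_state(self) -> float:
        return self._agg("steady_state_count")[0]

    @property
    def sd_steady_state(self) -> float:
        return self._agg("steady_state_count")[1]

    @property
    def n_censored(self) -> int:
        return int(self.table["censored"].sum())


def run_replicates(config: ModelConfig, geometry: Geometry,
                   placement: Placement, n: int, base_seed: int, *,
                   record: tuple = ("tg_bind", "tg_unbind"),
                   stop_after_bindings: int = 0,
                   t_end: float | None = None,
                   steady_state_fraction: float = 0.1) -> ReplicateSummary:
    """Run ``n`` independent replicates with derived seeds base_seed + i and
    summarise first-binding time, steady-state complex count (time average
    over the final fraction of the run) and half-max time per replicate.

    Censored replicates (no binding before the end) carry NaN finding times
    and are excluded from the means; the count is reported.
    """
    if n < 1:
        raise ValueError(f"need n >= 1 replicates, got {n}")
    from .observables import first_binding_time, half_max_time, steady_state_count

    rows = []
    for i in range(n):
        log = run_simulation(config, geometry, placement, seed=base_seed + i,
                             record=record,
                             stop_after_bindings=stop_after_bindings,
                             t_end=t_end)
        fbt = first_binding_time(log)
        ss = steady_state_count(log, final_fraction=steady_state_fraction)
        hm = half_max_time(log, ss) if ss > 0 else math.nan
        rows.append(dict(replicate=i, seed=base_seed + i,
                         first_binding_time=fbt,
                         censored=math.isnan(fbt),
                         steady_state_count=ss,
                         half_max_time=hm,
                         n_bind_events=log.n_events("tg_bind")))
    return ReplicateSummary(table=pd.DataFrame(rows), n=n,
                            base_seed=base_seed)
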