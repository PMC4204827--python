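"""The five in-silico experiments, end-to-end from configuration to tidy
result tables.

Each experiment is fully determined by its parameters and a base seed.  The
full-protocol defaults reproduce the published set-ups (antenna: 20 antennas
with centred targets and 50 searching TFs; hopping: 6 labelled TFs per
segment on 20 naked-DNA segments; IST modes: one 4,200 bp segment vs a stack
of ten 420 bp segments; mode combinations: a slide-linked 75 kb stack of 50
segments; dimensionality: point targets in 1D/2D/3D reflecting domains).
Replicate counts and virtual durations scale down without touching any
physical rate; scaled values are recorded in the returned metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel as K
from .config import ModelConfig
from .engine import Placement, run_simulation
from .geometry import GeometryLayout, StackSpec, build_geometry
from .observables import DistanceResponse, first_binding_time, steady_state_count

__all__ = [
    "ExperimentSpec",
    "experiment_antenna",
    "experiment_hopping",
    "experiment_ist_modes",
    "experiment_mode_combinations",
    "experiment_dimensionality",
    "estimate_mode_hazards",
    "MODE_COMBINATIONS",
    "run_experiment",
]


@dataclass
class ExperimentSpec:
    """Name + parameter overrides for one experiment run."""

    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.name!r}; "
                f"choose from {sorted(EXPERIMENTS)}")


def _antenna_geometry(config: ModelConfig, length_bp: int, n_segments: int):
    layout = GeometryLayout(
        stacks=[StackSpec(n_segments=n_segments, length_bp=length_bp)],
        tg=[(s, length_bp / 2.0) for s in range(n_segments)],
    )
    return build_geometry(config, layout)


def experiment_antenna(lengths_bp=(30, 60, 120, 210, 300, 450, 600, 1200, 2400),
                       koff_values=(11.6,), n_segments=20, n_tf=50,
                       replicates=20, t_end=3600.0, base_seed=0,
                       kon=1.7) -> tuple[pd.DataFrame, dict]:
    """Antenna effect: steady-state TF–TG complexes, first-binding time and
    half-max time as a function of antenna (segment) length, per koff.

    Targets sit at the centres of the antennas; TFs start at random 3D
    positions; specific binding is reversible (0.025 s⁻¹); no IST.
    """
    from .observables import half_max_time

    rows = []
    for koff in koff_values:
        for L in lengths_bp:
            config = ModelConfig(kon=kon, koff=koff, ist_graph_kind="none",
                                 k_complex_off=0.025, t_end=t_end)
            geom = _antenna_geometry(config, int(L), n_segments)
            per = {"ss": [], "first": [], "half": []}
            for r in range(replicates):
                log = run_simulation(
                    config, geom, Placement.random_free(n_tf),
                    seed=base_seed + 1000 * r + hash((int(L), float(koff))) % 997,
                    record=("tg_bind", "tg_unbind"))
                ss = steady_state_count(log)
                per["ss"].append(ss)
                per["first"].append(first_binding_time(log))
                per["half"].append(half_max_time(log, ss) if ss > 0 else math.nan)
            for key, label in (("ss", "steady_state"), ("first", "first_binding"),
                               ("half", "half_max")):
                x = np.array(per[key], dtype=float)
                ok = np.isfinite(x)
                rows.append(dict(
                    length_bp=int(L), koff=float(koff), statistic=label,
                    mean=float(x[ok].mean()) if ok.any() else math.nan,
                    sd=float(x[ok].std(ddof=1)) if ok.sum() > 1 else 0.0,
                    n=int(ok.sum()), n_censored=int((~ok).sum())))
    meta = dict(experiment="antenna", lengths_bp=list(map(int, lengths_bp)),
                koff_values=list(map(float, koff_values)),
                n_segments=n_segments, n_tf=n_tf, replicates=replicates,
                t_end=t_end, base_seed=base_seed, kon=kon)
    return pd.DataFrame(rows), meta


def experiment_hopping(kon_values=(1.7, 10.0), n_segments=20, segment_bp=930,
                       n_per_segment=6, spacing_bp=60, replicates=20,
                       t_end=3600.0, base_seed=0) -> tuple[pd.DataFrame, dict]:
    """Emergent hopping: labelled TFs start bound at fixed distances from a
    target on naked DNA with 1D sliding disabled; distance-dependent
    binding counts indicate hopping.

    Each of ``n_segments`` segments carries one TG at one end and
    ``n_per_segment`` TFs at multiples of ``spacing_bp`` away from it.
    Specific binding is irreversible, TGs accept multiple TFs, and TFs may
    unbind/rebind DNA but cannot slide.  Returns one row per
    (kon, distance, replicate) with the number of bound labels (out of
    ``n_segments``).
    """
    rows = []
    distances = [(k + 1) * spacing_bp for k in range(n_per_segment)]
    for kon in kon_values:
        config = ModelConfig(kon=kon, sliding_enabled=False,
                             k_complex_off=0.0, allow_multiple_tf_per_tg=True,
                             ist_graph_kind="none", t_end=t_end)
        layout = GeometryLayout(
            stacks=[StackSpec(n_segments=n_segments, length_bp=segment_bp)],
            tg=[(s, 0.0) for s in range(n_segments)],
        )
        geom = build_geometry(config, layout)
        entries = []
        labels = []
        for s in range(n_segments):
            for k, d in enumerate(distances):
                entries.append((s, float(d)))
                labels.append(k)
        labels = np.array(labels)
        for r in range(replicates):
            log = run_simulation(config, geom, Placement.bound(entries),
                                 seed=base_seed + r + int(kon * 1000) * 10007,
                                 record=("tg_bind",))
            complexed = log.final_mode == K.MODE_COMPLEXED
            for k, d in enumerate(distances):
                rows.append(dict(kon=float(kon), distance_bp=int(d),
                                 replicate=r,
                                 count=int(complexed[labels == k].sum())))
    meta = dict(experiment="hopping", kon_values=list(map(float, kon_values)),
                n_segments=n_segments, segment_bp=segment_bp,
                distances_bp=distances, replicates=replicates, t_end=t_end,
                base_seed=base_seed)
    return pd.DataFrame(rows), meta


def hopping_trend(df: pd.DataFrame, kon: float):
    """One-sided Spearman test for binding counts decreasing with start
    distance.  Returns (rho, p_value) over all (distance, replicate)
    pairs at the given kon."""
    from scipy import stats

    sub = df[df["kon"] == kon]
    rho, p_two = stats.spearmanr(sub["distance_bp"], sub["count"])
    p_one = p_two / 2.0 if rho < 0 else 1.0 - p_two / 2.0
    return float(rho), float(p_one)


def experiment_ist_modes(distances_bp=(420, 840, 1680, 2520, 3360),
                         replicates=20, t_end=600.0, base_seed=0,
                         segment_bp=420, n_segments=10,
                         sliding_segment_bp=4200) -> tuple[dict, dict]:
    """Finding time vs TF–TG distance for three search modes of a TF that is
    confined to the DNA (no desorption): pure 1D sliding on one long
    segment; "sequential" IST on a chain-connected stack; "concurrent" IST
    on an all-to-all-connected stack.

    In the IST modes the TG sits at one end of the last segment and the TF
    starts at the same axial position on an earlier segment, so the quoted
    distance is the total DNA length between TF and TG.
    """
    out = {}
    for mode in ("sliding", "sequential", "concurrent"):
        samples = {}
        for d in distances_bp:
            config = ModelConfig(
                koff=0.0, k_complex_off=0.0,
                ist_rate=11.6 if mode != "sliding" else 0.0,
                ist_graph_kind={"sliding": "none", "sequential": "chain",
                                "concurrent": "complete"}[mode],
                t_end=t_end)
            if mode == "sliding":
                if d > sliding_segment_bp:
                    continue
                layout = GeometryLayout(
                    stacks=[StackSpec(n_segments=1,
                                      length_bp=sliding_segment_bp)],
                    tg=[(0, 0.0)])
                entries = [(0, float(d))]
            else:
                hops = int(round(d / segment_bp))
                if not 1 <= hops <= n_segments - 1:
                    continue
                layout = GeometryLayout(
                    stacks=[StackSpec(n_segments=n_segments,
                                      length_bp=segment_bp)],
                    tg=[(n_segments - 1, float(segment_bp))])
                entries = [(n_segments - 1 - hops, float(segment_bp))]
            geom = build_geometry(config, layout)
            times = []
            for r in range(replicates):
                log = run_simulation(config, geom, Placement.bound(entries),
                                     seed=base_seed + r + d * 131,
                                     record=("tg_bind",),
                                     stop_after_bindings=1)
                times.append(first_binding_time(log))
            samples[float(d)] = np.array(times)
        out[mode] = DistanceResponse.from_samples(samples)
    meta = dict(experiment="ist_modes", distances_bp=list(distances_bp),
                replicates=replicates, t_end=t_end, base_seed=base_seed)
    return out, meta


# (3D level, 1D sliding on, IST on) — the nine tested combinations
MODE_COMBINATIONS = (
    ("standard", True, True),
    ("low", True, True),
    ("zero", True, True),
    ("standard", True, False),
    ("standard", False, True),
    ("standard", False, False),
    ("zero", True, False),
    ("zero", False, True),
    ("low", False, False),
)

_D3_LEVELS = {"standard": 2.72, "low": 0.0272, "zero": 0.0}


def _combo_config(d3_level: str, sliding: bool, ist: bool,
                  t_end: float) -> ModelConfig:
    D3 = _D3_LEVELS[d3_level]
    return ModelConfig(
        D3=D3,
        sliding_enabled=sliding,
        slide_linked=sliding,
        ist_graph_kind="chain" if ist else "none",
        ist_rate=11.6 if ist else 0.0,
        # with no 3D diffusion the TF is confined to the DNA
        koff=11.6 if D3 > 0 else 0.0,
        k_complex_off=0.0,
        allow_3d_tg_binding=True,
        t_end=t_end)


def _stack75_geometry(config: ModelConfig, n_segments=50, segment_bp=1500):
    layout = GeometryLayout(
        stacks=[StackSpec(n_segments=n_segments, length_bp=segment_bp)],
        tg=[(n_segments - 1, float(segment_bp))])
    return build_geometry(config, layout)


def experiment_mode_combinations(combos=MODE_COMBINATIONS, replicates=100,
                                 t_end=7200.0, base_seed=0, n_segments=50,
                                 segment_bp=1500) -> tuple[pd.DataFrame, dict]:
    """Single-TF finding times on a slide-linked 75 kb stack for
    combinations of 3D diffusion (standard / 100×-reduced / zero), 1D
    sliding and chain IST.

    The TF starts at one end of the DNA stack and the single TG sits at the
    opposite end; binding is irreversible and TFs in 3D space may bind the
    TG directly (same binding radius).  Censored replicates (no binding
    before ``t_end``) are excluded from means and counted.
    """
    rows = []
    for ci, (d3_level, sliding, ist) in enumerate(combos):
        config = _combo_config(d3_level, sliding, ist, t_end)
        geom = _stack75_geometry(config, n_segments, segment_bp)
        times = []
        for r in range(replicates):
            log = run_simulation(config, geom,
                                 Placement.bound([(0, 0.0)]),
                                 seed=base_seed + 100000 * ci + r,
                                 record=("tg_bind",),
                                 stop_after_bindings=1)
            times.append(first_binding_time(log))
        x = np.array(times, dtype=float)
        ok = np.isfinite(x)
        rows.append(dict(
            d3=d3_level, sliding=bool(sliding), ist=bool(ist),
            mean_finding_time=float(x[ok].mean()) if ok.any() else math.nan,
            sd_finding_time=float(x[ok].std(ddof=1)) if ok.sum() > 1 else 0.0,
            n=int(ok.sum()), n_censored=int((~ok).sum()),
            complexes_formed=int(ok.sum())))
    meta = dict(experiment="mode_combinations", replicates=replicates,
                t_end=t_end, base_seed=base_seed, n_segments=n_segments,
                segment_bp=segment_bp)
    return pd.DataFrame(rows), meta


def experiment_dimensionality(distances_um=(0.25, 0.5, 0.75), n_tf=5,
                              replicates=100, base_seed=0,
                              t_end={1: 20.0, 2: 60.0, 3: 6000.0},
                              dt={1: 1e-6, 2: 1e-6, 3: 1e-4},
                              D=2.72, sigma_b_nm=2.0,
                              box_half_um=1.0) -> tuple[dict, dict]:
    """Distance dependence of finding times in 1D, 2D and 3D systems, each
    2 µm across: a reflecting interval, square, or sphere with a point
    target at the centre, captured end-of-step within the binding radius.

    Per replicate, ``n_tf`` independent TFs start at the given distance and
    the replicate statistic is their mean binding time (censored TFs
    excluded and counted).  ``distances_um``, ``replicates``, ``t_end`` and
    ``dt`` may each be a single value or a {dimension: value} mapping (the
    3D system needs far longer runs per binding event than 1D/2D, and the
    cheap 1D/2D arms afford denser distance grids).  Returns
    {dimension: DistanceResponse}.
    """
    out = {}
    for ndim in (1, 2, 3):
        h = t_end[ndim] if isinstance(t_end, dict) else t_end
        step = dt[ndim] if isinstance(dt, dict) else dt
        reps = replicates[ndim] if isinstance(replicates, dict) else replicates
        dists = (distances_um[ndim] if isinstance(distances_um, dict)
                 else distances_um)
        max_steps = int(round(h / step))
        samples = {}
        for di, dist in enumerate(dists):
            rng = np.random.default_rng(base_seed + 7919 * ndim + 61 * di)
            means = []
            for r in range(reps):
                times = []
                for _ in range(n_tf):
                    s = K.dim_first_passage(ndim, float(dist), D, step,
                                            sigma_b_nm * 1e-3, max_steps,
                                            box_half_um, rng)
                    times.append(s * step if s > 0 else math.nan)
                t = np.array(times)
                ok = np.isfinite(t)
                means.append(float(t[ok].mean()) if ok.any() else math.nan)
            samples[float(dist) * 1e3] = np.array(means)  # distance key in nm
        out[ndim] = DistanceResponse.from_samples(samples)
    meta = dict(experiment="dimensionality",
                distances_um=list(map(float, distances_um)), n_tf=n_tf,
                replicates=replicates, base_seed=base_seed,
                t_end=dict(t_end) if isinstance(t_end, dict) else t_end,
                dt=dict(dt) if isinstance(dt, dict) else dt)
    return out, meta


def estimate_mode_hazards(n_tf=100, t_virtual=1800.0, base_seed=0,
                          n_segments=50, segment_bp=1500) -> tuple[pd.DataFrame, dict]:
    """Per-TF specific-binding hazard on the 75 kb stack for three
    configurations: 3D diffusion alone, 3D + 1D sliding, and 3D + IST.

    ``n_tf`` independent, non-interacting TFs start at random free
    positions; every binding event is recorded and the TF is immediately
    reset to a random free position (the TG is never depleted), so the
    hazard is events / (n_tf · t_virtual).  The returned table carries the
    fold-acceleration of each combined mode relative to 3D alone.
    """
    configs = {
        "3d_only": ("standard", False, False),
        "3d_sliding": ("standard", True, False),
        "3d_ist": ("standard", False, True),
    }
    rows = []
    for ci, (name, (lvl, sliding, ist)) in enumerate(configs.items()):
        config = _combo_config(lvl, sliding, ist, t_virtual)
        geom = _stack75_geometry(config, n_segments, segment_bp)
        log = run_simulation(config, geom, Placement.random_free(n_tf),
                             seed=base_seed + 7717 * ci,
                             record=("tg_bind",), non_depleting=True)
        events = log.n_events("tg_bind")
        rows.append(dict(configuration=name, events=events,
                         hazard_per_s=events / (n_tf * t_virtual)))
    df = pd.DataFrame(rows).set_index("configuration")
    base = df.loc["3d_only", "hazard_per_s"]
    df["fold_vs_3d_only"] = df["hazard_per_s"] / base if base > 0 else math.nan
    meta = dict(experiment="mode_hazards", n_tf=n_tf, t_virtual=t_virtual,
                base_seed=base_seed, n_segments=n_segments,
                segment_bp=segment_bp)
    return df.reset_index(), meta


EXPERIMENTS = {
    "antenna": experiment_antenna,
    "hopping": experiment_hopping,
    "ist_modes": experiment_ist_modes,
    "modes": experiment_mode_combinations,
    "dimensionality": experiment_dimensionality,
}


def run_experiment(spec: ExperimentSpec):
    """Dispatch an :class:`ExperimentSpec` to its experiment function."""
    return EXPERIMENTS[spec.name](**spec.params)
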