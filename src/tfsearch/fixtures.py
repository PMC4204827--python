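"""Synthetic inputs with known ground truth: oligomer tables, analytic
oracles, and resolved experiment configurations at any scale.

Everything here is reproducible from (parameters, seed), and generators
always emit the realised ground truth alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import OLIGOMER_STATES
from .experiments import ExperimentSpec

__all__ = [
    "FixtureSpec",
    "generate_oligomer_table",
    "oracle_mfpt_1d",
    "oracle_bound_fraction",
    "generate_experiment_config",
]


@dataclass
class FixtureSpec:
    kind: str  # geometry | oligomer_table | oracle_case
    params: dict = field(default_factory=dict)
    seed: int = 0


def generate_oligomer_table(class_specs, seed: int = 0,
                            deterministic: bool = False):
    """Generate an oligomer classification table with known class
    composition.

    ``class_specs`` is a list of (label, n, state_fractions) where
    ``state_fractions`` maps oligomeric states to fractions summing to 1.
    Stochastic mode draws a multinomial per class; deterministic mode
    requires every fraction × n to be integral and emits exact counts.

    Returns (table, ground_truth): the table is a DataFrame with columns
    ``protein_id``, ``class``, ``oligomeric_state``; the ground truth maps
    each class to its realised state counts.
    """
    rng = np.random.default_rng(seed)
    rows = []
    truth = {}
    pid = 0
    for label, n, fractions in class_specs:
        if n < 1:
            raise ValueError(f"class {label!r}: n must be >= 1")
        states = list(fractions)
        unknown = set(states) - set(OLIGOMER_STATES)
        if unknown:
            raise ValueError(f"unknown oligomeric states {sorted(unknown)}")
        p = np.array([fractions[s] for s in states], dtype=float)
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"class {label!r}: fractions sum to {p.sum():.6f}, not 1")
        if deterministic:
            counts = p * n
            if not np.allclose(counts, np.round(counts), atol=1e-9):
                raise ValueError(
                    f"class {label!r}: fractions × n not integral")
            counts = np.round(counts).astype(int)
        else:
            counts = rng.multinomial(n, p)
        truth[label] = {s: int(c) for s, c in zip(states, counts)}
        for s, c in zip(states, counts):
            for _ in range(c):
                rows.append((f"P{pid:06d}", label, s))
                pid += 1
    table = pd.DataFrame(rows, columns=["protein_id", "class",
                                        "oligomeric_state"])
    return table, truth


def oracle_mfpt_1d(x: float, L: float, D: float) -> float:
    """Mean first-passage time x(2L − x)/(2D) of a 1D diffuser started at
    offset ``x`` from an absorbing end, with a reflecting boundary at L.

    Closed-form oracle for pure-sliding target finding (e.g. the full
    4,200 bp segment, x = L = 1.428 µm at D = 0.0262 µm²/s, gives 38.9 s).
    """
    if D <= 0:
        raise ValueError(f"D must be > 0, got {D!r}")
    if not 0 < x <= L:
        raise ValueError(f"need 0 < x <= L, got x = {x!r}, L = {L!r}")
    return x * (2.0 * L - x) / (2.0 * D)


def oracle_bound_fraction(kon: float, koff: float, A: float, V: float) -> float:
    """Equilibrium bound fraction kon·A / (kon·A + koff·V) of a well-mixed
    adsorption–desorption balance (A = total face area µm², V = accessible
    volume µm³)."""
    if min(kon, koff, A, V) < 0:
        raise ValueError("all arguments must be >= 0")
    denom = kon * A + koff * V
    if denom == 0:
        raise ValueError("kon·A + koff·V must be > 0")
    return kon * A / denom


_FULL_SCALE = {
    "antenna": dict(replicates=20, t_end=3600.0),
    "hopping": dict(replicates=20, t_end=3600.0),
    "ist_modes": dict(replicates=20, t_end=600.0),
    "modes": dict(replicates=100, t_end=7200.0),
    "dimensionality": dict(replicates=100),
}


def generate_experiment_config(name: str, scale: float = 1.0,
                               seed: int = 0) -> ExperimentSpec:
    """Resolved, runnable configuration for one of the five experiments.

    ``scale`` ∈ (0, 1] shrinks replicate counts and virtual durations only
    — never a physical rate — so scaled runs probe the same physics with
    wider error bars.  Replicate counts keep a floor of 3.
    """
    if name not in _FULL_SCALE:
        raise ValueError(f"unknown experiment {name!r}; "
                         f"choose from {sorted(_FULL_SCALE)}")
    if not 0 < scale <= 1:
        raise ValueError(f"scale must be in (0, 1], got {scale!r}")
    params = dict(_FULL_SCALE[name])
    params["replicates"] = max(3, int(round(params["replicates"] * scale)))
    if "t_end" in params:
        params["t_end"] = max(60.0, params["t_end"] * scale)
    params["base_seed"] = seed
    return ExperimentSpec(name=name, params=params)
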