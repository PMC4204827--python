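"""Per-time-step stochastic propagators on single-TF states.

Thin, test-friendly wrappers around the compiled kernels in ``_kernel``; the
engine loop composes exactly the same kernels, so there is a single
implementation of every elementary process.

A TF is always in exactly one of three modes: FREE (3D position inside the
nucleus), BOUND (surface coordinates on a DNA face) or COMPLEXED (attached
to a target gene).  All coordinates here are in µm; ``ModelConfig.sigma_b``
is in nm and converted at this boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel as K
from .geometry import Geometry

__all__ = [
    "FREE", "BOUND", "COMPLEXED",
    "ParticleState",
    "rms_step", "sticking_probability", "event_probability",
    "step_free_3d", "step_bound_1d",
    "attempt_adsorption", "attempt_desorption", "attempt_ist",
    "check_tg_binding", "dissociate_complex",
]

FREE = K.MODE_FREE
BOUND = K.MODE_BOUND
COMPLEXED = K.MODE_COMPLEXED


@dataclass
class ParticleState:
    """One TF's mode and coordinates.

    Exactly one mode's coordinates are meaningful: ``position`` (µm) when
    FREE, ``(segment, u, v, face)`` (u, v in µm) when BOUND, ``tg`` when
    COMPLEXED.
    """

    tf_id: int = 0
    label: int = 0
    mode: int = FREE
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    segment: int = -1
    u: float = 0.0
    v: float = 0.0
    face: int = 0
    tg: int = -1

    def copy(self) -> "ParticleState":
        return ParticleState(self.tf_id, self.label, self.mode,
                             self.position.copy(), self.segment,
                             self.u, self.v, self.face, self.tg)


def rms_step(D: float, dt: float) -> float:
    """Per-axis rms displacement √(2·D·dt) of one diffusion step (µm)."""
    return math.sqrt(2.0 * D * dt)


def event_probability(rate: float, dt: float) -> float:
    """Exact per-step probability 1 − exp(−rate·dt) of a first-order event."""
    return -math.expm1(-rate * dt)


def sticking_probability(kon: float, D3: float, dt: float) -> float:
    """Per-crossing sticking probability that reproduces the macroscopic
    adsorption coefficient ``kon`` (µm/s) for a reflecting Gaussian walk:
    P = kon·√(π·dt/D3), clipped to 1."""
    if kon < 0:
        raise ValueError(f"kon must be >= 0, got {kon!r}")
    if kon == 0.0:
        return 0.0
    if D3 <= 0.0:
        return 0.0
    return min(1.0, kon * math.sqrt(math.pi * dt / D3))


def step_free_3d(state: ParticleState, D3: float, dt: float,
                 nucleus_radius: float, rng: np.random.Generator) -> ParticleState:
    """Free 3D diffusion with radial mirror reflection at the nuclear
    envelope (no DNA interaction; see :func:`attempt_adsorption`)."""
    if state.mode != FREE:
        raise ValueError("step_free_3d requires a FREE particle")
    out = state.copy()
    x, y, z = K.free_propose(state.position[0], state.position[1],
                             state.position[2], rms_step(D3, dt),
                             nucleus_radius, rng)
    out.position = np.array([x, y, z])
    return out


def step_bound_1d(state: ParticleState, geometry: Geometry, D1: float,
                  dt: float, rng: np.random.Generator) -> ParticleState:
    """On-surface diffusion: reflecting in v, reflecting (or slide-linked)
    in u at segment ends."""
    if state.mode != BOUND:
        raise ValueError("step_bound_1d requires a BOUND particle")
    out = state.copy()
    seg, u, v = K.step_bound_1d(geometry.arrays(), state.segment, state.u,
                                state.v, rms_step(D1, dt), rng)
    out.segment, out.u, out.v = int(seg), float(u), float(v)
    return out


def attempt_adsorption(state: ParticleState, proposed: np.ndarray,
                       geometry: Geometry, kon: float, D3: float, dt: float,
                       rng: np.random.Generator) -> ParticleState:
    """Trace the straight sub-step from the current FREE position to
    ``proposed`` against all DNA faces; each crossing sticks with the
    calibrated probability or reflects.  Returns a BOUND state at the
    crossing point, or a FREE state at the (possibly reflected) end point."""
    if state.mode != FREE:
        raise ValueError("attempt_adsorption requires a FREE particle")
    p = sticking_probability(kon, D3, dt)
    out = state.copy()
    ads, seg, u, v, fc, x, y, z = K.resolve_free_path(
        geometry.arrays(),
        state.position[0], state.position[1], state.position[2],
        float(proposed[0]), float(proposed[1]), float(proposed[2]), p, rng)
    if ads:
        out.mode = BOUND
        out.segment, out.u, out.v, out.face = int(seg), float(u), float(v), int(fc)
    else:
        out.position = np.array([x, y, z])
    return out


def attempt_desorption(state: ParticleState, geometry: Geometry, koff: float,
                       D3: float, dt: float,
                       rng: np.random.Generator) -> ParticleState:
    """Desorb with probability 1 − exp(−koff·dt); on desorption the TF
    re-enters solution along the outward face normal at a distance sampled
    as if it desorbed at a uniform time within the step (mean ≈ 0.53 rms
    steps; see ``_kernel.desorb_offset``)."""
    if state.mode != BOUND:
        raise ValueError("attempt_desorption requires a BOUND particle")
    if koff > 0 and rng.random() < event_probability(koff, dt):
        out = state.copy()
        x, y, z = K.surface_point(geometry.arrays(), state.segment, state.u,
                                  state.v, state.face,
                                  K.desorb_offset(rms_step(D3, dt), rng))
        x, y, z = K.reflect_sphere(x, y, z, geometry.nucleus_radius)
        out.mode = FREE
        out.position = np.array([x, y, z])
        out.segment = -1
        return out
    return state


def attempt_ist(state: ParticleState, geometry: Geometry, ist_rate: float,
                dt: float, rng: np.random.Generator,
                randomize_u: bool = False) -> ParticleState:
    """Intersegmental transfer to a uniformly chosen adjacent segment with
    probability 1 − exp(−rate·dt); no-op when the segment has no
    neighbours.  The axial coordinate is preserved (clamped) by default."""
    if state.mode != BOUND:
        raise ValueError("attempt_ist requires a BOUND particle")
    fired, seg, u = K.attempt_ist(geometry.arrays(), state.segment, state.u,
                                  event_probability(ist_rate, dt),
                                  randomize_u, rng)
    if not fired:
        return state
    out = state.copy()
    out.segment, out.u = int(seg), float(u)
    return out


def check_tg_binding(state: ParticleState, geometry: Geometry,
                     sigma_b_nm: float, tg_occupancy: np.ndarray,
                     tg_capacity: int = 1,
                     allow_3d_tg_binding: bool = False) -> ParticleState:
    """End-of-step specific-binding test: if the 3D distance to an eligible
    TG is ≤ the binding radius, the TF becomes COMPLEXED (occupancy is
    incremented in ``tg_occupancy``)."""
    sig = sigma_b_nm * 1e-3
    tg = -1
    if state.mode == BOUND:
        tg = K.check_tg_bound(geometry.arrays(), state.segment, state.u,
                              state.v, sig, tg_occupancy, tg_capacity)
    elif state.mode == FREE and allow_3d_tg_binding:
        tg = K.check_tg_free(geometry.arrays(), state.position[0],
                             state.position[1], state.position[2], sig,
                             tg_occupancy, tg_capacity)
    if tg < 0:
        return state
    out = state.copy()
    out.mode = COMPLEXED
    out.tg = int(tg)
    tg_occupancy[tg] += 1
    return out


def dissociate_complex(state: ParticleState, geometry: Geometry,
                       k_complex_off: float, D3: float, dt: float,
                       tg_occupancy: np.ndarray,
                       rng: np.random.Generator) -> ParticleState:
    """Complex dissociation at rate ``k_complex_off``: the TF re-enters 3D
    space just off the DNA face at the TG and occupancy is decremented."""
    if state.mode != COMPLEXED:
        raise ValueError("dissociate_complex requires a COMPLEXED particle")
    if k_complex_off > 0 and rng.random() < event_probability(k_complex_off, dt):
        out = state.copy()
        tg_occupancy[state.tg] -= 1
        x, y, z = K.tg_release_point(geometry.arrays(), state.tg,
                                     K.desorb_offset(rms_step(D3, dt), rng),
                                     rng)
        out.mode = FREE
        out.position = np.array([x, y, z])
        out.tg = -1
        return out
    return state
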