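"""Model configuration: physical parameters, mode switches, numerical settings.

All quantities are stored in the units used throughout the package:
lengths in µm (except ``sigma_b`` and ``rise_per_bp``, conventionally quoted
in nm), times in seconds, diffusion coefficients in µm²/s, the adsorption
coefficient in µm/s and first-order rates in 1/s.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields, asdict

__all__ = ["ModelConfig", "IST_GRAPH_KINDS"]

IST_GRAPH_KINDS = ("none", "chain", "complete")


@dataclass
class ModelConfig:
    """Every physical parameter, mode switch and numerical setting of a run.

    Defaults are the reference parameter set of the yeast-nucleus model:
    a transcription factor (TF) diffusing at 2.72 µm²/s in the nucleoplasm,
    sliding on DNA at 0.0262 µm²/s, adsorbing onto DNA faces with
    k_on = 1.7 µm/s (chromatinised DNA; 10 µm/s models protein-free DNA),
    desorbing at 11.6 s⁻¹, transferring between adjacent segments at
    11.6 s⁻¹ when intersegmental transfer (IST) is enabled, and binding a
    target gene (TG) within a 2.0 nm binding radius.  TF–TG complexes
    dissociate at 0.025 s⁻¹ when dissociation is enabled (0 = irreversible).

    Parameters
    ----------
    D3 : float
        3D diffusion coefficient in the nucleoplasm, µm²/s.
    D1 : float
        Diffusion coefficient on the DNA surface, µm²/s.
    kon : float
        Macroscopic adsorption coefficient onto DNA faces, µm/s.
    koff : float
        Non-specific TF–DNA dissociation rate, 1/s.
    ist_rate : float
        Total rate of intersegmental transfer events while DNA-bound, 1/s.
    sigma_b : float
        Specific binding radius around a target gene, nm.
    k_complex_off : float
        TF–TG complex dissociation rate, 1/s; 0 means irreversible binding.
    dt : float
        Time step, s.
    t_end : float
        Virtual duration of a run, s.
    allow_3d_tg_binding : bool
        If True, freely diffusing TFs may also bind TGs (end-of-step test
        with the same binding radius); by default only DNA-bound TFs can.
    allow_multiple_tf_per_tg : bool
        If True, a TG can hold any number of TFs; by default occupancy 1.
    sliding_enabled : bool
        Master switch for 1D sliding; when False the on-DNA diffusion
        coefficient is treated as zero.
    ist_graph_kind : str
        Segment connectivity used for IST: "none", "chain" (consecutive
        segments of a stack) or "complete" (all pairs within a stack).
    slide_linked : bool
        If True, the end of each segment of a stack is chained to the start
        of the next, so sliding carries over instead of reflecting.
    ist_randomize_u : bool
        If True, a transfer lands at a uniformly random axial position on
        the destination segment instead of preserving (and clamping) it.
    seed : int
        Base random seed.
    rise_per_bp : float
        Axial rise per basepair, nm (0.34 for B-DNA).
    """

    D3: float = 2.72
    D1: float = 0.0262
    kon: float = 1.7
    koff: float = 11.6
    ist_rate: float = 11.6
    sigma_b: float = 2.0
    k_complex_off: float = 0.025
    dt: float = 1e-4
    t_end: float = 3600.0
    allow_3d_tg_binding: bool = False
    allow_multiple_tf_per_tg: bool = False
    sliding_enabled: bool = True
    ist_graph_kind: str = "none"
    slide_linked: bool = False
    ist_randomize_u: bool = False
    seed: int = 0
    rise_per_bp: float = 0.34

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        import math

        for name in ("D3", "D1", "kon", "koff", "ist_rate", "k_complex_off"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if not (math.isfinite(self.dt) and self.dt > 0):
            raise ValueError(f"dt must be finite and > 0, got {self.dt!r}")
        if not (math.isfinite(self.sigma_b) and self.sigma_b > 0):
            raise ValueError(f"sigma_b must be finite and > 0, got {self.sigma_b!r}")
        if not (math.isfinite(self.t_end) and self.t_end >= 0):
            raise ValueError(f"t_end must be finite and >= 0, got {self.t_end!r}")
        if self.rise_per_bp <= 0:
            raise ValueError(f"rise_per_bp must be > 0, got {self.rise_per_bp!r}")
        if self.ist_graph_kind not in IST_GRAPH_KINDS:
            raise ValueError(
                f"ist_graph_kind must be one of {IST_GRAPH_KINDS}, "
                f"got {self.ist_graph_kind!r}"
            )

    @property
    def effective_D1(self) -> float:
        """On-DNA diffusion coefficient actually applied (0 if sliding off)."""
        return self.D1 if self.sliding_enabled else 0.0

    @property
    def sigma_b_um(self) -> float:
        return self.sigma_b * 1e-3

    def replace(self, **kwargs) -> "ModelConfig":
        d = asdict(self)
        d.update(kwargs)
        return ModelConfig(**d)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def hash(self) -> str:
        """Stable hash of the configuration (for run manifests)."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
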