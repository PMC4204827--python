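"""Configuration files, result serialisation and run manifests.

Configuration files are YAML with two optional sections::

    model:
      kon: 10.0          # any ModelConfig field; omitted fields keep the
      koff: 11.6         # reference defaults
    geometry:
      nucleus_radius: 0.75
      stacks:
        - n_segments: 10
          length_bp: 420
          spacing_nm: 10.0
      tg:
        - [9, 420]       # (segment id, position in bp)

Unknown keys are rejected with an error naming the key.  Results are written
as tidy CSV/TSV plus a manifest (JSON) recording the config snapshot, seeds,
package version and a checksum per output file, which is sufficient to
re-run any result byte-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from .config import ModelConfig
from .geometry import GeometryLayout, StackSpec

__all__ = ["parse_config", "dump_config", "write_results", "RunManifest"]

_GEOM_KEYS = {"nucleus_radius", "width_nm", "stacks", "tg"}
_STACK_KEYS = {f.name for f in fields(StackSpec)}


def parse_config(path) -> tuple[ModelConfig, GeometryLayout | None]:
    """Parse a YAML configuration file into a validated ModelConfig and an
    optional GeometryLayout.  An empty file yields all defaults and no
    geometry."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    unknown = set(data) - {"model", "geometry"}
    if unknown:
        raise ValueError(f"{path}: unknown top-level keys {sorted(unknown)}")
    model = ModelConfig.from_dict(data.get("model") or {})
    layout = None
    if "geometry" in data and data["geometry"] is not None:
        g = data["geometry"]
        unknown = set(g) - _GEOM_KEYS
        if unknown:
            raise ValueError(f"{path}: unknown geometry keys {sorted(unknown)}")
        stacks = []
        for i, s in enumerate(g.get("stacks") or []):
            bad = set(s) - _STACK_KEYS
            if bad:
                raise ValueError(
                    f"{path}: unknown stack keys {sorted(bad)} in stack {i}")
            stacks.append(StackSpec(**{k: (tuple(v) if isinstance(v, list)
                                           and k in ("center", "axis", "normal")
                                           else v)
                                       for k, v in s.items()}))
        layout = GeometryLayout(
            stacks=stacks,
            tg=[tuple(t) for t in (g.get("tg") or [])],
            nucleus_radius=g.get("nucleus_radius", 0.75),
            width_nm=g.get("width_nm", 2.6),
        )
    return model, layout


def dump_config(config: ModelConfig, layout: GeometryLayout | None,
                path) -> None:
    """Write a configuration back to YAML (inverse of :func:`parse_config`)."""
    data: dict = {"model": config.to_dict()}
    if layout is not None:
        data["geometry"] = {
            "nucleus_radius": layout.nucleus_radius,
            "width_nm": layout.width_nm,
            "stacks": [
                {k: v for k, v in asdict(s).items()}
                for s in layout.stacks
            ],
            "tg": [list(t) for t in layout.tg],
        }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to re-run a result byte-identically."""

    command: str
    seed: int
    config: dict
    version: str = ""
    outputs: dict = field(default_factory=dict)  # filename -> sha256

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def write_results(tables: dict[str, pd.DataFrame], manifest: RunManifest,
                  out_dir) -> dict[str, str]:
    """Write tidy CSV tables plus the manifest to ``out_dir``.

    The manifest is written first (so interrupted runs are detectable by a
    checksum mismatch), then each table, then the manifest again with the
    final file inventory.  Returns {filename: sha256}.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest.outputs = {}
    manifest.save(manifest_path)
    try:
        for name, df in tables.items():
            p = out / f"{name}.csv"
            df.to_csv(p, index=False)
            manifest.outputs[p.name] = _sha256(p)
    except OSError as e:
        raise OSError(f"failed writing results under {out}: {e}") from e
    manifest.save(manifest_path)
    return dict(manifest.outputs)
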