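"""Oligomeric-state enrichment analysis.

Sequence-specific DNA binding proteins can perform intersegmental transfer
only if they can bind two DNA segments at once, which dimers and tetramers
allow.  This stage takes a non-redundant protein classification table —
rows of (protein id, functional class, oligomeric state) — and computes
per-class dimer/tetramer percentages and the enrichment of the combined
dimer + tetramer fraction relative to a non-DNA-binding control class
(typically oxidoreductases).

The table is pure input: any TSV with columns ``protein_id``, ``class`` and
``oligomeric_state`` conforms (see :func:`read_oligomer_table`); the test
surface uses synthetic tables with known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "OLIGOMER_STATES", "PROTEIN_CLASSES",
    "read_oligomer_table", "write_oligomer_table",
    "class_multimer_percentages", "enrichment_vs_control",
    "EnrichmentResult",
]

OLIGOMER_STATES = ("monomer", "dimer", "trimer", "tetramer", "higher")
PROTEIN_CLASSES = ("transcription", "DNA binding", "transferase",
                   "oxidoreductase", "other")

_COLUMNS = ["protein_id", "class", "oligomeric_state"]


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"oligomer table missing columns {missing}")
    if len(table) == 0:
        raise ValueError("oligomer table is empty")
    if table["protein_id"].duplicated().any():
        dup = table.loc[table["protein_id"].duplicated(), "protein_id"].iloc[0]
        raise ValueError(f"protein ids must be unique (duplicate {dup!r})")
    bad = set(table["oligomeric_state"]) - set(OLIGOMER_STATES)
    if bad:
        raise ValueError(f"unknown oligomeric states {sorted(bad)}; "
                         f"expected one of {OLIGOMER_STATES}")
    return table


def read_oligomer_table(path) -> pd.DataFrame:
    """Read a tab-separated oligomer table with header
    ``protein_id  class  oligomeric_state``."""
    return _validate(pd.read_csv(path, sep="\t"))


def write_oligomer_table(table: pd.DataFrame, path) -> None:
    _validate(table).to_csv(path, sep="\t", index=False)


def class_multimer_percentages(table: pd.DataFrame) -> pd.DataFrame:
    """Per-class percentages of dimers, tetramers and everything else
    (monomers, trimers, higher oligomers), with the underlying counts.

    Percentages within a class sum to 100 up to rounding.  Classes with no
    rows simply do not appear.
    """
    _validate(table)
    rows = []
    for cls, sub in table.groupby("class", sort=True):
        n = len(sub)
        n_dimer = int((sub["oligomeric_state"] == "dimer").sum())
        n_tetramer = int((sub["oligomeric_state"] == "tetramer").sum())
        n_other = n - n_dimer - n_tetramer
        rows.append(dict(
            **{"class": cls},
            n=n, n_dimer=n_dimer, n_tetramer=n_tetramer, n_other=n_other,
            pct_dimer=100.0 * n_dimer / n,
            pct_tetramer=100.0 * n_tetramer / n,
            pct_other=100.0 * n_other / n,
            pct_dimer_tetramer=100.0 * (n_dimer + n_tetramer) / n,
        ))
    return pd.DataFrame(rows)


@dataclass
class EnrichmentResult:
    """Enrichment of the dimer+tetramer fraction of one class over a
    control class, with a two-proportion normal-approximation CI for the
    ratio (reported as an optional annotation; the primary quantity is the
    ratio of fractions)."""

    cls: str
    control: str
    class_fraction: float
    control_fraction: float
    ratio: float
    ci: tuple[float, float]
    n_class: int
    n_control: int


def enrichment_vs_control(table: pd.DataFrame, cls: str,
                          control: str = "oxidoreductase",
                          confidence: float = 0.95) -> EnrichmentResult:
    """Ratio of (dimer + tetramer) fractions between ``cls`` and
    ``control``.  The CI is a log-normal approximation for a risk ratio.
    A zero control fraction yields an infinite (undefined) ratio."""
    from scipy import stats

    _validate(table)
    frac = {}
    n = {}
    k = {}
    for name in (cls, control):
        sub = table[table["class"] == name]
        if len(sub) == 0:
            raise ValueError(f"class {name!r} is empty or absent")
        n[name] = len(sub)
        k[name] = int(sub["oligomeric_state"].isin(["dimer", "tetramer"]).sum())
        frac[name] = k[name] / n[name]
    if frac[control] == 0:
        ratio = math.inf
        ci = (math.nan, math.nan)
    else:
        ratio = frac[cls] / frac[control]
        if k[cls] == 0:
            ci = (0.0, math.nan)
        else:
            se = math.sqrt((1 - frac[cls]) / k[cls]
                           + (1 - frac[control]) / k[control])
            z = stats.norm.ppf(0.5 + confidence / 2.0)
            ci = (ratio * math.exp(-z * se), ratio * math.exp(z * se))
    return EnrichmentResult(cls=cls, control=control,
                            class_fraction=frac[cls],
                            control_fraction=frac[control],
                            ratio=ratio, ci=ci,
                            n_class=n[cls], n_control=n[control])
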