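"""Composite histology indices for colitis and lung inflammation.

Two human-graded rubrics are scored:

* Mouse colitis histology index: a weighted sum over four components —
  goblet cell loss (0-3), crypt density (0-2), crypt hyperplasia (0-3)
  and submucosal infiltration (0-3) — with weights 1, 2, 2 and 3, giving
  a range of 0..22.
* Lung inflammation histology index: perivascular infiltration graded
  0-5 at five randomly chosen blood vessels; the index is the sum of the
  five vessel scores, range 0..25.

Grading itself is a human input; this module only validates and scores.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Sequence

import pandas as pd

COLITIS_WEIGHTS = {
    "goblet_cell_loss": 1,
    "crypt_density": 2,
    "crypt_hyperplasia": 2,
    "submucosal_infiltration": 3,
}
COLITIS_RANGES = {
    "goblet_cell_loss": (0, 3),
    "crypt_density": (0, 2),
    "crypt_hyperplasia": (0, 3),
    "submucosal_infiltration": (0, 3),
}
COLITIS_MAX = 22
LUNG_VESSELS = 5
LUNG_SCORE_RANGE = (0, 5)
LUNG_MAX = 25


@dataclass(frozen=True)
class ColitisComponents:
    """Integer grades of the four colitis rubric components."""

    goblet_cell_loss: int
    crypt_density: int
    crypt_hyperplasia: int
    submucosal_infiltration: int

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            lo, hi = COLITIS_RANGES[f.name]
            if not (isinstance(value, int) and lo <= value <= hi):
                raise ValueError(f"{f.name} must be an integer in {lo}..{hi}, got {value!r}")


@dataclass(frozen=True)
class LungVesselScores:
    """Perivascular infiltration grades at exactly five vessels."""

    vessel_scores: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.vessel_scores) != LUNG_VESSELS:
            raise ValueError(f"exactly {LUNG_VESSELS} vessel scores required, got {len(self.vessel_scores)}")
        lo, hi = LUNG_SCORE_RANGE
        for v in self.vessel_scores:
            if not (isinstance(v, int) and lo <= v <= hi):
                raise ValueError(f"vessel score must be an integer in {lo}..{hi}, got {v!r}")


def colitis_index(c: ColitisComponents) -> int:
    """1*goblet + 2*crypt density + 2*crypt hyperplasia + 3*submucosal."""
    return sum(COLITIS_WEIGHTS[f.name] * getattr(c, f.name) for f in fields(c))


def lung_index(v: LungVesselScores) -> int:
    """Sum of the five per-vessel scores."""
    return sum(v.vessel_scores)


def score_colitis_table(df: pd.DataFrame) -> pd.DataFrame:
    """Score a batch of specimens from a grades table.

    Expects columns ``specimen_id`` plus the four component names; returns
    (specimen_id, index).
    """
    required = ["specimen_id", *COLITIS_WEIGHTS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    out = []
    for row in df.to_dict("records"):
        comp = ColitisComponents(**{k: int(row[k]) for k in COLITIS_WEIGHTS})
        out.append({"specimen_id": row["specimen_id"], "index": colitis_index(comp)})
    return pd.DataFrame(out)


def score_lung_table(df: pd.DataFrame) -> pd.DataFrame:
    """Score a batch of specimens with columns specimen_id, vessel_1..vessel_5."""
    vessel_cols = [f"vessel_{i}" for i in range(1, LUNG_VESSELS + 1)]
    missing = [c for c in ["specimen_id", *vessel_cols] if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    out = []
    for row in df.to_dict("records"):
        scores = LungVesselScores(tuple(int(row[c]) for c in vessel_cols))
        out.append({"specimen_id": row["specimen_id"], "index": lung_index(scores)})
    return pd.DataFrame(out)
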