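"""Cohort CSV schema, JSON artifact serialisation and run configuration.

The cohort CSV is long-format, one row per participant-tooth:
``participant_id, sex, age_years, tooth_fdi, hard_ml, hsst_ml, lsst_ml``
with UTF-8 encoding and decimal points.  Model artifacts are JSON with a
``schema_version`` field and are written deterministically (sorted keys,
repr-roundtrip floats) so identical runs produce identical bytes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

COHORT_COLUMNS = (
    "participant_id",
    "sex",
    "age_years",
    "tooth_fdi",
    "hard_ml",
    "hsst_ml",
    "lsst_ml",
)

VALID_TEETH = frozenset({16, 17, 26, 27, 36, 37, 46, 47})


class CohortValidationError(ValueError):
    """Raised when a cohort file violates the schema."""


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV; row errors carry 1-based line numbers."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, encoding="utf-8")
    return validate_cohort(df)


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing required columns: {missing}")
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        if row.sex not in ("F", "M"):
            errors.append(f"line {i}: sex must be 'F' or 'M', got {row.sex!r}")
        if not row.age_years > 0:
            errors.append(f"line {i}: age_years must be > 0")
        if int(row.tooth_fdi) not in VALID_TEETH:
            errors.append(f"line {i}: tooth_fdi {row.tooth_fdi} is not a 1st/2nd molar")
        for col in ("hard_ml", "hsst_ml", "lsst_ml"):
            if not getattr(row, col) > 0:
                errors.append(
                    f"line {i}: {col} violates the positive-volume invariant"
                )
    dup = df.duplicated(subset=["participant_id", "tooth_fdi"])
    if dup.any():
        for i in df.index[dup]:
            errors.append(
                f"line {i + 2}: duplicate (participant_id, tooth_fdi) = "
                f"({df.loc[i, 'participant_id']}, {df.loc[i, 'tooth_fdi']})"
            )
    if errors:
        raise CohortValidationError("; ".join(errors))
    out = df.copy()
    out["tooth_fdi"] = out["tooth_fdi"].astype(int)
    return out


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort CSV losslessly (17 significant digits)."""
    df.to_csv(path, index=False, float_format="%.17g", encoding="utf-8")


def dump_json(obj: dict, path: str | Path) -> None:
    """Deterministic JSON writer: sorted keys, newline-terminated."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_json(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def config_hash(cfg: dict) -> str:
    """Stable short hash of a JSON-serialisable config."""
    canon = json.dumps(cfg, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


class RunConfig(BaseModel):
    """Validated end-to-end pipeline configuration."""

    prior_lower: float = 14.0
    prior_upper: float = 23.0
    threshold_age: float = 18.0
    grid_step: float = Field(default=0.01, gt=0, le=0.05)
    outcomes: Sequence[str] | None = None  # None -> screen decides
    tooth_sets: Sequence[Sequence[int]] | None = None
    structure: str | None = None  # override AIC selection
    weighting: str | None = None
    redundancy_threshold: float = Field(default=0.999, gt=0, le=1)
    n_hypothetical: int = Field(default=4, ge=1)
    combine_teeth: Sequence[Sequence[int]] | None = None  # e.g. [[46], [47]]
    seed: int = 0
    verbose: bool = False

    @field_validator("outcomes")
    @classmethod
    def _check_outcomes(cls, v):
        from .transforms import OUTCOME_CODES

        if v is not None:
            bad = [c for c in v if c not in OUTCOME_CODES]
            if bad:
                raise ValueError(f"unknown outcome code(s): {bad}")
        return v

    @model_validator(mode="after")
    def _check_bounds(self):
        if not self.prior_lower < self.threshold_age < self.prior_upper:
            raise ValueError("prior bounds must bracket the threshold age")
        if self.structure is not None and self.structure not in (
            "i", "ii", "iii", "iv", "v",
        ):
            raise ValueError(f"unknown sex structure {self.structure!r}")
        if self.weighting is not None and self.weighting not in (
            "constant", "age", "inv_age",
        ):
            raise ValueError(f"unknown variance weighting {self.weighting!r}")
        return self
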