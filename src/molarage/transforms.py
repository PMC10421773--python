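"""The ten tissue-volume transformation outcomes and the redundancy screen.

Outcome codes:

* ``1``            total = hard + hsst + lsst
* ``2a/2b/2c``     x / (total - x)           with x = hsst / lsst / hard
* ``3a/3b/3c``     x / total                 with x = hsst / lsst / hard
* ``4a/4b/4c``     (x + y) / total           pairs (hsst+lsst), (hsst+hard),
                   (lsst+hard)

Analyses downstream use the natural log of the outcome.  Outcomes whose
log-scale absolute Pearson correlation with another outcome reaches the
overlap threshold (default 0.999) are redundant; within an overlapping
pair the family-2 member is the one dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .voxel import ToothVolumes

__all__ = [
    "OUTCOME_CODES",
    "FAMILY2_CODES",
    "OVERLAP_THRESHOLD",
    "outcome_values",
    "compute_outcomes",
    "log_outcome_matrix",
    "RedundancyReport",
    "screen_redundancy",
]

OUTCOME_CODES = ("1", "2a", "2b", "2c", "3a", "3b", "3c", "4a", "4b", "4c")
FAMILY2_CODES = ("2a", "2b", "2c")
OVERLAP_THRESHOLD = 0.999

_VOLUME_COLS = ("hard_ml", "hsst_ml", "lsst_ml")


def outcome_values(code, hard, hsst, lsst):
    """Evaluate one outcome; accepts scalars or aligned arrays."""
    hard = np.asarray(hard, dtype=float)
    hsst = np.asarray(hsst, dtype=float)
    lsst = np.asarray(lsst, dtype=float)
    if np.any(hard <= 0) or np.any(hsst <= 0) or np.any(lsst <= 0):
        raise ValueError("all tissue volumes must be > 0")
    total = hard + hsst + lsst
    match code:
        case "1":
            out = total
        case "2a":
            out = hsst / (total - hsst)
        case "2b":
            out = lsst / (total - lsst)
        case "2c":
            out = hard / (total - hard)
        case "3a":
            out = hsst / total
        case "3b":
            out = lsst / total
        case "3c":
            out = hard / total
        case "4a":
            out = (hsst + lsst) / total
        case "4b":
            out = (hsst + hard) / total
        case "4c":
            out = (lsst + hard) / total
        case _:
            raise ValueError(f"unknown outcome code {code!r}")
    return out if out.ndim else float(out)


def compute_outcomes(v: ToothVolumes) -> dict[str, float]:
    """All ten outcomes for one tooth's volumes."""
    return {c: outcome_values(c, v.hard, v.hsst, v.lsst) for c in OUTCOME_CODES}


def log_outcome_matrix(cohort: pd.DataFrame, codes=OUTCOME_CODES) -> pd.DataFrame:
    """Natural-log outcomes per cohort row, columns named by code."""
    missing = [c for c in _VOLUME_COLS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort is missing volume columns {missing}")
    hard = cohort["hard_ml"].to_numpy(dtype=float)
    hsst = cohort["hsst_ml"].to_numpy(dtype=float)
    lsst = cohort["lsst_ml"].to_numpy(dtype=float)
    data = {c: np.log(outcome_values(c, hard, hsst, lsst)) for c in codes}
    return pd.DataFrame(data, index=cohort.index)


@dataclass
class RedundancyReport:
    threshold: float
    retained: tuple[str, ...]
    dropped: tuple[str, ...]
    overlap_pairs: tuple[tuple[str, str, float], ...]
    indeterminate: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "retained": list(self.retained),
            "dropped": list(self.dropped),
            "overlap_pairs": [list(p) for p in self.overlap_pairs],
            "indeterminate": [list(p) for p in self.indeterminate],
        }


def screen_redundancy(
    logs: pd.DataFrame, threshold: float = OVERLAP_THRESHOLD
) -> RedundancyReport:
    """Flag outcome pairs whose |Pearson R| on the log scale >= ``threshold``.

    Family-2 outcomes overlapping any other outcome are dropped, so on
    realistic tooth-volume data seven codes are retained.  Constant
    columns have undefined correlation and are reported as indeterminate.
    """
    if len(logs) < 3:
        raise ValueError("redundancy screen needs at least 3 rows")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    codes = [c for c in logs.columns]
    X = logs.to_numpy(dtype=float)
    sd = X.std(axis=0)
    pairs: list[tuple[str, str, float]] = []
    indeterminate: list[tuple[str, str]] = []
    for i in range(len(codes)):
        for j in range(i + 1, len(codes)):
            if sd[i] == 0 or sd[j] == 0:
                indeterminate.append((codes[i], codes[j]))
                continue
            r = float(np.corrcoef(X[:, i], X[:, j])[0, 1])
            if abs(r) >= threshold:
                pairs.append((codes[i], codes[j], r))
    dropped = set()
    for a, b, _ in pairs:
        for c, other in ((a, b), (b, a)):
            if c in FAMILY2_CODES and other not in dropped:
                dropped.add(c)
    retained = tuple(c for c in codes if c not in dropped)
    return RedundancyReport(
        threshold=threshold,
        retained=retained,
        dropped=tuple(sorted(dropped)),
        overlap_pairs=tuple(pairs),
        indeterminate=tuple(indeterminate),
    )
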