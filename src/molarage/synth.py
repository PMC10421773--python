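"""Synthetic cohort generation calibrated to printed tissue-volume statistics.

Cohorts are drawn from the same generative structure the analysis
assumes: per participant an age and sex; per tooth a latent log soft
fraction ((hsst+lsst)/total) from a linear-in-age model with variance
sigma^2 * v(age) and equicorrelated between-tooth residuals; a
log-normal total volume; and a fixed hsst:lsst split.  Defaults are
calibrated so that median volumes at the median age match the printed
per-sex, per-molar medians (e.g. male 2nd-molar hard 1.1 ml, HSST
0.070 ml, LSST 0.028 ml).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .regression import variance_multiplier

__all__ = [
    "TEETH",
    "MEDIAN_VOLUMES",
    "TABLE_COUNTS",
    "SyntheticConfig",
    "generate_cohort",
    "fig4_replica_config",
]

TEETH = (16, 17, 26, 27, 36, 37, 46, 47)

#: printed median (hard, hsst, lsst) in ml per (sex, molar class)
MEDIAN_VOLUMES: dict[tuple[str, str], tuple[float, float, float]] = {
    ("F", "m1"): (1.1, 0.041, 0.021),
    ("M", "m1"): (1.2, 0.058, 0.028),
    ("F", "m2"): (1.0, 0.047, 0.021),
    ("M", "m2"): (1.1, 0.070, 0.028),
}

#: printed per-sex included-molar counts by FDI tooth
TABLE_COUNTS: dict[tuple[str, int], int] = {
    ("M", 16): 26, ("M", 26): 26, ("M", 36): 26, ("M", 46): 25,
    ("M", 17): 33, ("M", 27): 30, ("M", 37): 26, ("M", 47): 29,
    ("F", 16): 56, ("F", 26): 58, ("F", 36): 52, ("F", 46): 50,
    ("F", 17): 56, ("F", 27): 58, ("F", 37): 54, ("F", 47): 56,
}

_MEDIAN_AGE = 19.0  # median of the default uniform 14-24 age range


def molar_class(tooth: int) -> str:
    """'m1' for 1st molars (x6), 'm2' for 2nd molars (x7)."""
    pos = tooth % 10
    if pos == 6:
        return "m1"
    if pos == 7:
        return "m2"
    raise ValueError(f"tooth {tooth} is not a 1st or 2nd molar")


def _default_targets() -> dict[tuple[str, str], float]:
    out = {}
    for key, (hard, hsst, lsst) in MEDIAN_VOLUMES.items():
        total = hard + hsst + lsst
        out[key] = float(np.log((hsst + lsst) / total))
    return out


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort generator."""

    n_f: int = 60
    n_m: int = 33
    age_min: float = 14.0
    age_max: float = 24.0
    #: log soft-fraction slope per year, per sex
    slope: dict[str, float] = field(
        default_factory=lambda: {"F": -0.055, "M": -0.045}
    )
    #: intercepts per (sex, molar class); None -> calibrated so the mean
    #: log soft fraction at the median age matches the printed medians
    intercept: dict[tuple[str, str], float] | None = None
    sigma: float = 1.2
    weighting: str = "inv_age"
    rho: float = 0.62
    hsst_lsst_ratio: dict[tuple[str, str], float] | None = None
    total_median: dict[tuple[str, str], float] | None = None
    total_log_sd: float = 0.15
    #: exact per-(sex, tooth) inclusion counts; overrides missing_rate
    included_counts: dict[tuple[str, int], int] | None = None
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_f < 0 or self.n_m < 0 or self.n_f + self.n_m == 0:
            raise ValueError("cohort size must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not -1.0 / (len(TEETH) - 1) < self.rho < 1:
            raise ValueError("rho outside the positive-definite range")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.intercept is None:
            targets = _default_targets()
            self.intercept = {
                key: t - self.slope[key[0]] * _MEDIAN_AGE
                for key, t in targets.items()
            }
        if self.hsst_lsst_ratio is None:
            self.hsst_lsst_ratio = {
                key: hsst / lsst for key, (_, hsst, lsst) in MEDIAN_VOLUMES.items()
            }
        if self.total_median is None:
            self.total_median = {
                key: hard + hsst + lsst
                for key, (hard, hsst, lsst) in MEDIAN_VOLUMES.items()
            }


def _equicorr_cholesky(dim: int, rho: float) -> np.ndarray:
    C = np.full((dim, dim), rho)
    np.fill_diagonal(C, 1.0)
    return np.linalg.cholesky(C)


def generate_cohort(cfg: SyntheticConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw a synthetic cohort; bit-identical for a fixed seed."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    L = _equicorr_cholesky(len(TEETH), cfg.rho)

    frames = []
    for sex, n in (("F", cfg.n_f), ("M", cfg.n_m)):
        if n == 0:
            continue
        ages = rng.uniform(cfg.age_min, cfg.age_max, n)
        eps = rng.standard_normal((n, len(TEETH))) @ L.T
        sd = cfg.sigma * np.sqrt(variance_multiplier(cfg.weighting, ages))
        total_z = rng.standard_normal((n, len(TEETH)))
        recs = {
            "participant_id": np.repeat([f"{sex}{i:04d}" for i in range(n)], len(TEETH)),
            "sex": sex,
            "age_years": np.repeat(ages, len(TEETH)),
            "tooth_fdi": np.tile(TEETH, n),
        }
        hard = np.empty((n, len(TEETH)))
        hsst = np.empty((n, len(TEETH)))
        lsst = np.empty((n, len(TEETH)))
        for j, tooth in enumerate(TEETH):
            mc = molar_class(tooth)
            log_frac = (
                cfg.intercept[(sex, mc)] + cfg.slope[sex] * ages + sd * eps[:, j]
            )
            frac = np.exp(log_frac)
            if np.any(frac >= 1.0):
                raise ValueError(
                    "config produced soft fraction >= 1 (non-positive hard volume)"
                )
            total = cfg.total_median[(sex, mc)] * np.exp(
                cfg.total_log_sd * total_z[:, j]
            )
            soft = frac * total
            r = cfg.hsst_lsst_ratio[(sex, mc)]
            hard[:, j] = total - soft
            hsst[:, j] = soft * r / (1.0 + r)
            lsst[:, j] = soft / (1.0 + r)
        recs["hard_ml"] = hard.ravel()
        recs["hsst_ml"] = hsst.ravel()
        recs["lsst_ml"] = lsst.ravel()
        frames.append(pd.DataFrame(recs))
    cohort = pd.concat(frames, ignore_index=True)

    if cfg.included_counts is not None:
        keep = np.zeros(len(cohort), dtype=bool)
        for (sex, tooth), count in sorted(cfg.included_counts.items()):
            idx = cohort.index[
                (cohort["sex"] == sex) & (cohort["tooth_fdi"] == tooth)
            ].to_numpy()
            if count > len(idx):
                raise ValueError(
                    f"included count {count} for ({sex}, {tooth}) exceeds "
                    f"cohort size {len(idx)}"
                )
            keep[rng.choice(idx, size=count, replace=False)] = True
        cohort = cohort[keep]
    elif cfg.missing_rate > 0:
        keep = rng.uniform(size=len(cohort)) >= cfg.missing_rate
        cohort = cohort[keep]
    return cohort.reset_index(drop=True)


def fig4_replica_config(seed: int = 0) -> SyntheticConfig:
    """Config whose cohorts mimic the printed per-tooth sample sizes and the
    negative, sex-structured, 1/age-heteroscedastic age trends of the
    soft-fraction outcome."""
    return SyntheticConfig(included_counts=dict(TABLE_COUNTS), seed=seed)


def with_overrides(cfg: SyntheticConfig, **kwargs) -> SyntheticConfig:
    """Functional update helper (dataclasses.replace passthrough)."""
    return replace(cfg, **kwargs)
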