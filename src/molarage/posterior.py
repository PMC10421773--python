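"""Bayesian age prediction from an observed log-outcome.

A uniform age prior (default 14-23 years) is combined with the Gaussian
predictive density of the fitted regression model; the posterior is
normalised on a fine age grid by the trapezoid rule and summarised by
the probability of being older than the threshold age (default 18).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .regression import FittedModel

__all__ = ["AgePrior", "PosteriorResult", "likelihood", "posterior_age"]

DEFAULT_GRID_STEP = 0.01
DEFAULT_THRESHOLD = 18.0


@dataclass(frozen=True)
class AgePrior:
    """Uniform prior age distribution on [lower, upper] years."""

    lower: float = 14.0
    upper: float = 23.0

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("prior lower bound must be below upper bound")

    def grid(self, step: float) -> np.ndarray:
        if step <= 0 or step > 0.05:
            raise ValueError("grid step must be in (0, 0.05] years")
        n = int(round((self.upper - self.lower) / step))
        return np.linspace(self.lower, self.upper, n + 1)


@dataclass
class PosteriorResult:
    """Gridded posterior age density and threshold-exceedance probability."""

    ages: np.ndarray
    density: np.ndarray
    p_over: float
    threshold: float
    observed: float | dict[str, float]
    sex: str
    extras: dict = field(default_factory=dict)

    def mean(self) -> float:
        return float(np.trapezoid(self.ages * self.density, self.ages))

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "ages": self.ages.tolist(),
            "density": self.density.tolist(),
            "p_over": self.p_over,
            "threshold": self.threshold,
            "observed": self.observed,
            "sex": self.sex,
            **self.extras,
        }


def likelihood(
    y: float,
    age,
    sex: str,
    model: FittedModel,
    include_param_uncertainty: bool = True,
):
    """Gaussian predictive density of log-outcome ``y`` at the given age(s).

    The variance is sigma^2 * v(age) plus, by default, the parameter
    uncertainty term x' Cov(beta) x, matching the plotted prediction
    interval width.
    """
    mu = model.predict_mean(age, sex)
    var = model.predict_var(age, sex, include_param_uncertainty)
    return stats.norm.pdf(y, loc=mu, scale=np.sqrt(var))


def _integrate_over(ages: np.ndarray, density: np.ndarray, threshold: float) -> float:
    """Trapezoid integral of density over (threshold, max(ages)]."""
    if threshold <= ages[0]:
        return float(np.trapezoid(density, ages))
    if threshold >= ages[-1]:
        return 0.0
    i = int(np.searchsorted(ages, threshold, side="left"))
    if ages[i] > threshold:  # threshold between grid points: split the cell
        d_thr = np.interp(threshold, ages, density)
        a = np.concatenate([[threshold], ages[i:]])
        d = np.concatenate([[d_thr], density[i:]])
        return float(np.trapezoid(d, a))
    return float(np.trapezoid(density[i:], ages[i:]))


def posterior_age(
    y: float,
    sex: str,
    model: FittedModel,
    prior: AgePrior | None = None,
    grid_step: float = DEFAULT_GRID_STEP,
    threshold: float = DEFAULT_THRESHOLD,
    include_param_uncertainty: bool = True,
) -> PosteriorResult:
    """Posterior age density for one observed log-outcome and P(age > threshold)."""
    prior = prior or AgePrior()
    ages = prior.grid(grid_step)
    like = likelihood(y, ages, sex, model, include_param_uncertainty)
    norm = float(np.trapezoid(like, ages))
    if norm <= 0 or not np.isfinite(norm):
        raise ValueError("observation incompatible with model support")
    density = like / norm
    p_over = _integrate_over(ages, density, threshold)
    return PosteriorResult(
        ages=ages,
        density=density,
        p_over=min(max(p_over, 0.0), 1.0),
        threshold=threshold,
        observed=y,
        sex=sex,
    )
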