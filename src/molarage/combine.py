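"""Two-molar combination: bivariate normal likelihood with correlation.

The log-outcomes of two teeth share age/sex-dependent marginal mean and
variance structures (inherited from the single-tooth model selection)
plus a free correlation parameter rho, constant in age and sex.  All
parameters — both marginal coefficient vectors, both scales and rho —
are estimated jointly by maximum likelihood; participants with only one
of the two teeth contribute their marginal normal density.  Internally
rho is optimised on the Fisher-z scale and the scales on the log scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .posterior import (
    DEFAULT_GRID_STEP,
    DEFAULT_THRESHOLD,
    AgePrior,
    PosteriorResult,
)
from .regression import (
    FittedModel,
    ModelError,
    _design,
    build_response,
    fit_wls,
    variance_multiplier,
)

__all__ = ["MarginalSpec", "BivariateFit", "fit_bivariate", "posterior_age_combined"]

_RHO_BOUNDARY = 0.999


@dataclass(frozen=True)
class MarginalSpec:
    """One tooth's response definition and regression structure."""

    outcome: str
    teeth: tuple[int, ...]
    structure: str
    weighting: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "teeth", tuple(int(t) for t in self.teeth))
        if self.structure == "v":
            raise ModelError(
                "structure v (separate per-sex models) is not supported in the "
                "combination model; fit each sex separately instead"
            )

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "teeth": list(self.teeth),
            "structure": self.structure,
            "weighting": self.weighting,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MarginalSpec":
        return cls(d["outcome"], tuple(d["teeth"]), d["structure"], d["weighting"])


@dataclass
class BivariateFit:
    """Jointly ML-estimated two-tooth model."""

    spec_a: MarginalSpec
    spec_b: MarginalSpec
    model_a: FittedModel
    model_b: FittedModel
    rho: float
    loglik: float
    n_pairs: int
    n_a_only: int
    n_b_only: int
    converged: bool = True

    def marginal_model(self, which: str) -> FittedModel:
        if which not in ("a", "b"):
            raise ValueError("which must be 'a' or 'b'")
        return self.model_a if which == "a" else self.model_b

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "spec_a": self.spec_a.to_dict(),
            "spec_b": self.spec_b.to_dict(),
            "model_a": self.model_a.to_dict(),
            "model_b": self.model_b.to_dict(),
            "rho": self.rho,
            "loglik": self.loglik,
            "n_pairs": self.n_pairs,
            "n_a_only": self.n_a_only,
            "n_b_only": self.n_b_only,
            "converged": self.converged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BivariateFit":
        return cls(
            spec_a=MarginalSpec.from_dict(d["spec_a"]),
            spec_b=MarginalSpec.from_dict(d["spec_b"]),
            model_a=FittedModel.from_dict(d["model_a"]),
            model_b=FittedModel.from_dict(d["model_b"]),
            rho=d["rho"],
            loglik=d["loglik"],
            n_pairs=d["n_pairs"],
            n_a_only=d["n_a_only"],
            n_b_only=d["n_b_only"],
            converged=d.get("converged", True),
        )


def _merge_responses(cohort: pd.DataFrame, spec_a: MarginalSpec, spec_b: MarginalSpec):
    ra = build_response(cohort, spec_a.outcome, spec_a.teeth).rename(
        columns={"response": "y_a"}
    )[["participant_id", "sex", "age", "y_a"]]
    rb = build_response(cohort, spec_b.outcome, spec_b.teeth).rename(
        columns={"response": "y_b"}
    )[["participant_id", "sex", "age", "y_b"]]
    merged = ra.merge(rb, on=["participant_id", "sex", "age"], how="outer")
    return merged.sort_values("participant_id").reset_index(drop=True)


def _neg_loglik_factory(merged: pd.DataFrame, spec_a: MarginalSpec, spec_b: MarginalSpec):
    age = merged["age"].to_numpy(dtype=float)
    male = (merged["sex"].to_numpy() == "M").astype(float)
    ya = merged["y_a"].to_numpy(dtype=float)
    yb = merged["y_b"].to_numpy(dtype=float)
    has_a = ~np.isnan(ya)
    has_b = ~np.isnan(yb)
    both = has_a & has_b

    Xa, names_a = _design(spec_a.structure, age, male)
    Xb, names_b = _design(spec_b.structure, age, male)
    pa, pb = Xa.shape[1], Xb.shape[1]
    va = variance_multiplier(spec_a.weighting, age)
    vb = variance_multiplier(spec_b.weighting, age)
    log2pi = np.log(2.0 * np.pi)

    def neg_loglik(theta: np.ndarray) -> float:
        beta_a = theta[:pa]
        beta_b = theta[pa : pa + pb]
        sa2 = np.exp(2.0 * theta[pa + pb])
        sb2 = np.exp(2.0 * theta[pa + pb + 1])
        rho = np.tanh(theta[pa + pb + 2])
        var_a = sa2 * va
        var_b = sb2 * vb
        za = (ya - Xa @ beta_a) / np.sqrt(var_a)
        zb = (yb - Xb @ beta_b) / np.sqrt(var_b)
        ll = 0.0
        # complete pairs: bivariate normal
        if np.any(both):
            q = (
                za[both] ** 2 - 2.0 * rho * za[both] * zb[both] + zb[both] ** 2
            ) / (1.0 - rho**2)
            ll += float(
                np.sum(
                    -log2pi
                    - 0.5 * np.log(var_a[both] * var_b[both] * (1.0 - rho**2))
                    - 0.5 * q
                )
            )
        # singletons: marginal normal
        only_a = has_a & ~has_b
        only_b = has_b & ~has_a
        if np.any(only_a):
            ll += float(
                np.sum(-0.5 * (log2pi + np.log(var_a[only_a]) + za[only_a] ** 2))
            )
        if np.any(only_b):
            ll += float(
                np.sum(-0.5 * (log2pi + np.log(var_b[only_b]) + zb[only_b] ** 2))
            )
        return -ll

    meta = {
        "pa": pa,
        "pb": pb,
        "names_a": names_a,
        "names_b": names_b,
        "n_pairs": int(both.sum()),
        "n_a_only": int((has_a & ~has_b).sum()),
        "n_b_only": int((has_b & ~has_a).sum()),
        "has_a": has_a,
        "has_b": has_b,
    }
    return neg_loglik, meta


def _plugin_model(base: FittedModel, spec: MarginalSpec, beta, sigma2, n) -> FittedModel:
    """FittedModel carrying joint-ML parameters; no coefficient covariance."""
    return FittedModel(
        structure=spec.structure,
        weighting=spec.weighting,
        param_names=list(base.param_names),
        params=np.asarray(beta, dtype=float),
        cov=None,
        sigma2_ml=float(sigma2),
        s2=float(sigma2),
        n=n,
        df_resid=base.df_resid,
        k=base.k,
        loglik=float("nan"),
        aic=float("nan"),
        age_pvalues=dict(base.age_pvalues),
        outcome=spec.outcome,
        tooth_set=spec.teeth,
        sexes=base.sexes,
    )


def fit_bivariate(
    cohort: pd.DataFrame, spec_a: MarginalSpec, spec_b: MarginalSpec
) -> BivariateFit:
    """Joint maximum-likelihood fit of the two-tooth bivariate normal model.

    Initialised from the separate single-tooth WLS fits and the moment
    estimate of the residual correlation on complete pairs.
    """
    merged = _merge_responses(cohort, spec_a, spec_b)
    neg_loglik, meta = _neg_loglik_factory(merged, spec_a, spec_b)
    if meta["n_pairs"] < 3:
        raise ModelError("need at least 3 participants with both teeth")

    fa = fit_wls(
        merged[meta["has_a"]].rename(columns={"y_a": "response"}),
        spec_a.structure,
        spec_a.weighting,
    )
    fb = fit_wls(
        merged[meta["has_b"]].rename(columns={"y_b": "response"}),
        spec_b.structure,
        spec_b.weighting,
    )

    # moment estimate of rho from standardised residuals on complete pairs
    pairs = merged.dropna(subset=["y_a", "y_b"])
    age_p = pairs["age"].to_numpy(dtype=float)
    za0 = (
        pairs["y_a"].to_numpy() - np.array([fa.predict_mean(a, s) for a, s in zip(age_p, pairs["sex"])])
    ) / np.sqrt(fa.s2 * variance_multiplier(spec_a.weighting, age_p))
    zb0 = (
        pairs["y_b"].to_numpy() - np.array([fb.predict_mean(a, s) for a, s in zip(age_p, pairs["sex"])])
    ) / np.sqrt(fb.s2 * variance_multiplier(spec_b.weighting, age_p))
    rho0 = float(np.clip(np.corrcoef(za0, zb0)[0, 1], -0.95, 0.95))
    if not np.isfinite(rho0):
        rho0 = 0.0

    theta0 = np.concatenate(
        [
            fa.params,
            fb.params,
            [0.5 * np.log(fa.sigma2_ml), 0.5 * np.log(fb.sigma2_ml)],
            [np.arctanh(rho0)],
        ]
    )
    res = optimize.minimize(neg_loglik, theta0, method="BFGS", options={"gtol": 1e-8})
    if not res.success:
        res2 = optimize.minimize(
            neg_loglik,
            res.x,
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 20000},
        )
        if res2.fun <= res.fun:
            res = res2
    if not res.success and not np.isfinite(res.fun):
        raise ModelError(f"bivariate ML did not converge: {res.message}")

    pa, pb = meta["pa"], meta["pb"]
    beta_a = res.x[:pa]
    beta_b = res.x[pa : pa + pb]
    sa2 = float(np.exp(2.0 * res.x[pa + pb]))
    sb2 = float(np.exp(2.0 * res.x[pa + pb + 1]))
    rho = float(np.tanh(res.x[pa + pb + 2]))
    if abs(rho) >= _RHO_BOUNDARY:
        warnings.warn(
            f"correlation estimate |rho|={abs(rho):.4f} is at the boundary",
            stacklevel=2,
        )
    return BivariateFit(
        spec_a=spec_a,
        spec_b=spec_b,
        model_a=_plugin_model(fa, spec_a, beta_a, sa2, fa.n),
        model_b=_plugin_model(fb, spec_b, beta_b, sb2, fb.n),
        rho=rho,
        loglik=-float(res.fun),
        n_pairs=meta["n_pairs"],
        n_a_only=meta["n_a_only"],
        n_b_only=meta["n_b_only"],
        converged=bool(res.success),
    )


def _joint_density(fit: BivariateFit, ya, yb, ages: np.ndarray, sex: str) -> np.ndarray:
    mu_a = np.asarray(fit.model_a.predict_mean(ages, sex))
    mu_b = np.asarray(fit.model_b.predict_mean(ages, sex))
    var_a = np.asarray(fit.model_a.predict_var(ages, sex, False))
    var_b = np.asarray(fit.model_b.predict_var(ages, sex, False))
    rho = fit.rho
    za = (ya - mu_a) / np.sqrt(var_a)
    zb = (yb - mu_b) / np.sqrt(var_b)
    q = (za**2 - 2.0 * rho * za * zb + zb**2) / (1.0 - rho**2)
    return np.exp(-0.5 * q) / (
        2.0 * np.pi * np.sqrt(var_a * var_b * (1.0 - rho**2))
    )


def posterior_age_combined(
    y_a: float | None,
    y_b: float | None,
    sex: str,
    fit: BivariateFit,
    prior: AgePrior | None = None,
    grid_step: float = DEFAULT_GRID_STEP,
    threshold: float = DEFAULT_THRESHOLD,
) -> PosteriorResult:
    """Posterior age density from one or both teeth's observed log-outcomes.

    With both observations present the bivariate density is used; a
    missing tooth falls back to the marginal, making the result identical
    to the single-tooth posterior under the joint parameter estimates.
    The single-tooth exceedance probabilities are reported alongside for
    comparison.
    """
    from .posterior import _integrate_over, posterior_age

    if y_a is None and y_b is None:
        raise ValueError("at least one of the two observations must be present")
    prior = prior or AgePrior()
    ages = prior.grid(grid_step)

    if y_a is not None and y_b is not None:
        like = _joint_density(fit, y_a, y_b, ages, sex)
    elif y_a is not None:
        return posterior_age(
            y_a, sex, fit.model_a, prior, grid_step, threshold,
            include_param_uncertainty=False,
        )
    else:
        return posterior_age(
            y_b, sex, fit.model_b, prior, grid_step, threshold,
            include_param_uncertainty=False,
        )

    norm = float(np.trapezoid(like, ages))
    if norm <= 0 or not np.isfinite(norm):
        raise ValueError("observations incompatible with model support")
    density = like / norm
    p_over = _integrate_over(ages, density, threshold)

    extras = {}
    for key, y, model in (("a", y_a, fit.model_a), ("b", y_b, fit.model_b)):
        single = posterior_age(
            y, sex, model, prior, grid_step, threshold,
            include_param_uncertainty=False,
        )
        extras[f"p_over_{key}"] = single.p_over
    return PosteriorResult(
        ages=ages,
        density=density,
        p_over=min(max(p_over, 0.0), 1.0),
        threshold=threshold,
        observed={"a": y_a, "b": y_b},
        sex=sex,
        extras=extras,
    )
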