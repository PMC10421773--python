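"""Weighted linear regression grid over sex structures and variance weightings.

The mean of the log-outcome is linear in age under one of five sex
structures:

* ``i``    common intercept and slope (sex ignored)
* ``ii``   per-sex intercept, common slope
* ``iii``  common intercept, per-sex slope
* ``iv``   per-sex intercept and slope
* ``v``    fully separate per-sex models (also separate residual scale)

The observation variance is sigma^2 * v(age) with v one of ``constant``
(v=1), ``age`` (v=age) or ``inv_age`` (v=1/age); estimation is weighted
least squares with weights 1/v(age).  AIC (with sigma counted as a
parameter, the ``lm`` log-likelihood convention) selects the structure
and weighting; candidate outcomes and tooth sets are ranked by the
smallest per-sex age p-value of their AIC-selected model.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SEX_STRUCTURES",
    "VARIANCE_WEIGHTINGS",
    "ModelError",
    "FittedModel",
    "variance_multiplier",
    "build_response",
    "fit_wls",
    "select_structure",
    "rank_candidates",
]

SEX_STRUCTURES = ("i", "ii", "iii", "iv", "v")
VARIANCE_WEIGHTINGS = ("constant", "age", "inv_age")

_AIC_TIE_TOL = 1e-9


class ModelError(ValueError):
    """Raised for unfittable model specifications."""


def variance_multiplier(weighting: str, age) -> np.ndarray:
    """v(age) in Var(eps) = sigma^2 * v(age)."""
    age = np.asarray(age, dtype=float)
    if np.any(age <= 0):
        raise ModelError("ages must be positive")
    match weighting:
        case "constant":
            return np.ones_like(age)
        case "age":
            return age
        case "inv_age":
            return 1.0 / age
        case _:
            raise ValueError(f"unknown variance weighting {weighting!r}")


def _design(structure: str, age: np.ndarray, male: np.ndarray):
    """Design matrix and parameter names for one sex structure.

    Structures iii/iv use a per-sex-slope parameterisation so each sex's
    age coefficient has its own t-test.
    """
    one = np.ones_like(age)
    female = 1.0 - male
    match structure:
        case "i":
            return np.column_stack([one, age]), ["intercept", "age"]
        case "ii":
            return np.column_stack([one, male, age]), ["intercept", "sex_M", "age"]
        case "iii":
            return (
                np.column_stack([one, age * female, age * male]),
                ["intercept", "age_F", "age_M"],
            )
        case "iv":
            return (
                np.column_stack([female, male, age * female, age * male]),
                ["intercept_F", "intercept_M", "age_F", "age_M"],
            )
        case _:
            raise ValueError(f"unknown sex structure {structure!r}")


@dataclass
class FittedModel:
    """A fitted weighted regression (or, for structure v, a per-sex pair)."""

    structure: str
    weighting: str
    param_names: list[str]
    params: np.ndarray
    cov: np.ndarray | None
    sigma2_ml: float
    s2: float
    n: int
    df_resid: int
    k: int
    loglik: float
    aic: float
    age_pvalues: dict[str, float]
    outcome: str | None = None
    tooth_set: tuple[int, ...] | None = None
    submodels: dict[str, "FittedModel"] | None = None
    sexes: tuple[str, ...] = ("F", "M")

    # ---- prediction -------------------------------------------------
    def _row(self, age, sex: str):
        age = np.atleast_1d(np.asarray(age, dtype=float))
        male = np.full_like(age, 1.0 if sex == "M" else 0.0)
        X, _ = _design(self.structure, age, male)
        return X

    def _dispatch(self, sex: str) -> "FittedModel":
        if self.structure == "v":
            if self.submodels is None or sex not in self.submodels:
                raise ModelError(f"no structure-v submodel for sex {sex!r}")
            return self.submodels[sex]
        return self

    def predict_mean(self, age, sex: str):
        """Fitted mean log-outcome at the given age(s) for one sex."""
        m = self._dispatch(sex)
        out = m._row(age, sex) @ m.params
        return out if np.ndim(age) else float(out[0])

    def predict_var(self, age, sex: str, include_param_uncertainty: bool = True):
        """Predictive variance for a new observation at age: residual part
        s^2 * v(age) plus, optionally, the x' Cov(beta) x term."""
        m = self._dispatch(sex)
        age_arr = np.atleast_1d(np.asarray(age, dtype=float))
        var = m.s2 * variance_multiplier(m.weighting, age_arr)
        if include_param_uncertainty and m.cov is not None:
            X = m._row(age_arr, sex)
            var = var + np.einsum("ij,jk,ik->i", X, m.cov, X)
        return var if np.ndim(age) else float(var[0])

    def prediction_interval(self, age, sex: str, level: float = 0.95):
        """Two-sided t prediction interval for a new log-outcome."""
        m = self._dispatch(sex)
        mu = np.asarray(self.predict_mean(age, sex))
        sd = np.sqrt(np.asarray(self.predict_var(age, sex)))
        q = stats.t.ppf(0.5 + level / 2.0, m.df_resid)
        lo, hi = mu - q * sd, mu + q * sd
        if np.ndim(age):
            return lo, hi
        return float(lo), float(hi)

    # ---- serialisation ----------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "schema_version": 1,
            "structure": self.structure,
            "weighting": self.weighting,
            "param_names": list(self.param_names),
            "params": np.asarray(self.params).tolist(),
            "cov": None if self.cov is None else np.asarray(self.cov).tolist(),
            "sigma2_ml": self.sigma2_ml,
            "s2": self.s2,
            "n": self.n,
            "df_resid": self.df_resid,
            "k": self.k,
            "loglik": self.loglik,
            "aic": self.aic,
            "age_pvalues": dict(self.age_pvalues),
            "outcome": self.outcome,
            "tooth_set": None if self.tooth_set is None else list(self.tooth_set),
            "sexes": list(self.sexes),
            "submodels": None
            if self.submodels is None
            else {s: m.to_dict() for s, m in self.submodels.items()},
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        return cls(
            structure=d["structure"],
            weighting=d["weighting"],
            param_names=list(d["param_names"]),
            params=np.asarray(d["params"], dtype=float),
            cov=None if d["cov"] is None else np.asarray(d["cov"], dtype=float),
            sigma2_ml=d["sigma2_ml"],
            s2=d["s2"],
            n=d["n"],
            df_resid=d["df_resid"],
            k=d["k"],
            loglik=d["loglik"],
            aic=d["aic"],
            age_pvalues={k: float(v) for k, v in d["age_pvalues"].items()},
            outcome=d.get("outcome"),
            tooth_set=None if d.get("tooth_set") is None else tuple(d["tooth_set"]),
            sexes=tuple(d.get("sexes", ("F", "M"))),
            submodels=None
            if d.get("submodels") is None
            else {s: cls.from_dict(m) for s, m in d["submodels"].items()},
        )


def build_response(
    cohort: pd.DataFrame, outcome: str, tooth_set
) -> pd.DataFrame:
    """Per-participant response for one outcome over a tooth set.

    The response is the mean of the log-outcome across the participant's
    available teeth in the set; participants with no qualifying tooth are
    excluded.  Returns columns participant_id, sex, age, response.
    """
    from .transforms import log_outcome_matrix

    tooth_set = tuple(int(t) for t in tooth_set)
    if not tooth_set:
        raise ValueError("tooth set must be non-empty")
    sub = cohort[cohort["tooth_fdi"].isin(tooth_set)]
    if sub.empty:
        raise ModelError(
            f"no usable observations for outcome {outcome} teeth {tooth_set}"
        )
    logs = log_outcome_matrix(sub, codes=(outcome,))
    sub = sub.assign(response=logs[outcome].to_numpy())
    resp = (
        sub.groupby("participant_id", sort=True)
        .agg(
            sex=("sex", "first"),
            age=("age_years", "first"),
            response=("response", "mean"),
            n_teeth=("tooth_fdi", "size"),
        )
        .reset_index()
    )
    return resp


def _fit_single(age, male, y, structure, weighting):
    X, names = _design(structure, age, male)
    n, p = X.shape
    if n < p:
        raise ModelError(
            f"structure {structure}: need at least {p} observations, got {n}"
        )
    v = variance_multiplier(weighting, age)
    w = 1.0 / v
    Xw = X * w[:, None]
    A = X.T @ Xw
    if np.linalg.matrix_rank(A) < p:
        raise ModelError(f"singular design for structure {structure}")
    Ainv = np.linalg.inv(A)
    beta = Ainv @ (Xw.T @ y)
    resid = y - X @ beta
    rss_w = float(np.sum(w * resid**2))
    sigma2_ml = rss_w / n
    df_resid = n - p
    # degenerate exact fits (rss 0 or saturated design) get nan inference
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = rss_w / df_resid if df_resid > 0 else float("nan")
        # ML Gaussian log-likelihood; +0.5*sum(log w) accounts for v(age).
        loglik = -0.5 * n * (
            np.log(2 * np.pi) + np.log(sigma2_ml) + 1.0
        ) + 0.5 * float(np.sum(np.log(w)))
        cov = s2 * Ainv
        se = np.sqrt(np.diag(cov))
        tvals = beta / se
    if df_resid > 0:
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    else:
        pvals = np.full(p, np.nan)
    return X, names, beta, cov, sigma2_ml, s2, rss_w, df_resid, loglik, dict(
        zip(names, pvals)
    )


def fit_wls(
    responses: pd.DataFrame,
    structure: str,
    weighting: str,
    outcome: str | None = None,
    tooth_set=None,
) -> FittedModel:
    """Fit one cell of the (sex structure x variance weighting) grid."""
    if structure not in SEX_STRUCTURES:
        raise ValueError(f"unknown sex structure {structure!r}")
    if weighting not in VARIANCE_WEIGHTINGS:
        raise ValueError(f"unknown variance weighting {weighting!r}")
    age = responses["age"].to_numpy(dtype=float)
    y = responses["response"].to_numpy(dtype=float)
    sex = responses["sex"].to_numpy()
    sexes_present = tuple(s for s in ("F", "M") if s in sex)
    male = (sex == "M").astype(float)
    ts = None if tooth_set is None else tuple(int(t) for t in tooth_set)

    if structure == "v":
        if len(sexes_present) < 2:
            raise ModelError("structure v needs both sexes present")
        subs = {}
        for s in sexes_present:
            m = sex == s
            subs[s] = fit_wls(
                responses[m], "i", weighting, outcome=outcome, tooth_set=ts
            )
        loglik = sum(m.loglik for m in subs.values())
        k = sum(m.k for m in subs.values())
        aic = sum(m.aic for m in subs.values())
        age_p = {s: m.age_pvalues[s] for s, m in subs.items()}
        return FittedModel(
            structure="v",
            weighting=weighting,
            param_names=[f"{s}:{n}" for s, m in subs.items() for n in m.param_names],
            params=np.concatenate([m.params for m in subs.values()]),
            cov=None,
            sigma2_ml=float("nan"),
            s2=float("nan"),
            n=sum(m.n for m in subs.values()),
            df_resid=sum(m.df_resid for m in subs.values()),
            k=k,
            loglik=loglik,
            aic=aic,
            age_pvalues=age_p,
            outcome=outcome,
            tooth_set=ts,
            submodels=subs,
            sexes=sexes_present,
        )

    if structure in ("ii", "iii", "iv") and len(sexes_present) < 2:
        raise ModelError(f"singular design for structure {structure}: one sex absent")

    _, names, beta, cov, sigma2_ml, s2, _, df_resid, loglik, pvals = _fit_single(
        age, male, y, structure, weighting
    )
    k = len(beta) + 1  # sigma counted as a parameter
    aic = 2.0 * k - 2.0 * loglik
    if structure in ("i", "ii"):
        age_p = {s: pvals["age"] for s in sexes_present}
    else:
        age_p = {s: pvals[f"age_{s}"] for s in sexes_present}
    return FittedModel(
        structure=structure,
        weighting=weighting,
        param_names=names,
        params=beta,
        cov=cov,
        sigma2_ml=sigma2_ml,
        s2=s2,
        n=len(y),
        df_resid=df_resid,
        k=k,
        loglik=loglik,
        aic=aic,
        age_pvalues=age_p,
        outcome=outcome,
        tooth_set=ts,
        sexes=sexes_present,
    )


def select_structure(
    responses: pd.DataFrame,
    structures=SEX_STRUCTURES,
    weightings=VARIANCE_WEIGHTINGS,
    outcome: str | None = None,
    tooth_set=None,
) -> FittedModel:
    """Fit the whole grid and return the AIC-minimising model.

    Unfittable cells are skipped with a warning.  AIC ties (within 1e-9)
    go to the model with fewer parameters, then to grid-enumeration order.
    """
    best: FittedModel | None = None
    for s, w in itertools.product(structures, weightings):
        try:
            m = fit_wls(responses, s, w, outcome=outcome, tooth_set=tooth_set)
        except ModelError as exc:
            warnings.warn(f"skipping ({s}, {w}): {exc}", stacklevel=2)
            continue
        if best is None or m.aic < best.aic - _AIC_TIE_TOL:
            best = m
        elif abs(m.aic - best.aic) <= _AIC_TIE_TOL and m.k < best.k:
            best = m
    if best is None:
        raise ModelError("no fittable cell in the structure/weighting grid")
    return best


def rank_candidates(
    cohort: pd.DataFrame,
    outcomes,
    tooth_sets,
    structures=SEX_STRUCTURES,
    weightings=VARIANCE_WEIGHTINGS,
) -> pd.DataFrame:
    """Rank (outcome, tooth set) candidates by their smallest age p-value.

    Each candidate is fitted with its own AIC-selected structure and
    weighting; per-sex p-values are reported alongside the ranking key.
    """
    tooth_sets = [tuple(int(t) for t in ts) for ts in tooth_sets]
    if not outcomes or not tooth_sets:
        raise ValueError("need at least one outcome and one tooth set")
    rows = []
    for code in outcomes:
        for ts in tooth_sets:
            try:
                resp = build_response(cohort, code, ts)
                m = select_structure(
                    resp, structures, weightings, outcome=code, tooth_set=ts
                )
            except ModelError as exc:
                warnings.warn(f"skipping candidate ({code}, {ts}): {exc}", stacklevel=2)
                continue
            rows.append(
                {
                    "outcome": code,
                    "teeth": "+".join(str(t) for t in ts),
                    "structure": m.structure,
                    "weighting": m.weighting,
                    "aic": m.aic,
                    "n": m.n,
                    "p_F": m.age_pvalues.get("F", np.nan),
                    "p_M": m.age_pvalues.get("M", np.nan),
                    "p_min": min(m.age_pvalues.values()),
                }
            )
    if not rows:
        raise ModelError("no fittable candidates")
    table = pd.DataFrame(rows).sort_values("p_min", kind="mergesort")
    table.insert(0, "rank", range(1, len(table) + 1))
    return table.reset_index(drop=True)
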