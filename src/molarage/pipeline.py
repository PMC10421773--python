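"""End-to-end orchestration: screen -> rank -> fit -> predict (-> combine)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import __version__
from .combine import MarginalSpec, fit_bivariate, posterior_age_combined
from .io import RunConfig, config_hash
from .posterior import AgePrior, posterior_age
from .regression import (
    SEX_STRUCTURES,
    VARIANCE_WEIGHTINGS,
    build_response,
    select_structure,
)
from .transforms import OUTCOME_CODES, log_outcome_matrix, screen_redundancy

__all__ = [
    "SINGLE_TEETH",
    "TOOTH_COMBINATIONS",
    "default_tooth_sets",
    "hypothetical_observations",
    "run_pipeline",
]

SINGLE_TEETH = tuple((t,) for t in (16, 17, 26, 27, 36, 37, 46, 47))

# The seven printed within-molar-type combinations, for each molar type.
_COMBO_PATTERN = (
    (1, 2),        # upper both sides
    (3, 4),        # lower both sides
    (1, 4),        # upper and lower right
    (2, 3),        # upper and lower left
    (1, 3),        # upper right and lower left
    (2, 4),        # upper left and lower right
    (1, 2, 3, 4),  # all four
)
TOOTH_COMBINATIONS = tuple(
    tuple(10 * q + pos for q in quads)
    for pos in (6, 7)
    for quads in _COMBO_PATTERN
)


def default_tooth_sets():
    return SINGLE_TEETH + TOOTH_COMBINATIONS


def hypothetical_observations(responses: np.ndarray, n: int = 4) -> np.ndarray:
    """n values in uniform intervals strictly between the observed min and max."""
    lo, hi = float(np.min(responses)), float(np.max(responses))
    return np.linspace(lo, hi, n + 2)[1:-1]


def _structures(cfg: RunConfig):
    return (cfg.structure,) if cfg.structure else SEX_STRUCTURES


def _weightings(cfg: RunConfig):
    return (cfg.weighting,) if cfg.weighting else VARIANCE_WEIGHTINGS


def run_pipeline(cohort: pd.DataFrame, cfg: RunConfig) -> dict:
    """Run the full analysis on a validated cohort; returns the report bundle.

    Stages: redundancy screen over the ten log outcomes, candidate
    ranking by age p-value, best-model fit, posterior age prediction for
    hypothetical observations placed in uniform intervals between the
    observed extremes and, when configured, the two-tooth combination.
    """
    from .regression import rank_candidates

    prior = AgePrior(cfg.prior_lower, cfg.prior_upper)

    # 1. redundancy screen
    logs = log_outcome_matrix(cohort, OUTCOME_CODES)
    screen = screen_redundancy(logs, cfg.redundancy_threshold)

    # 2. candidate ranking
    outcomes = tuple(cfg.outcomes) if cfg.outcomes else screen.retained
    tooth_sets = (
        tuple(tuple(ts) for ts in cfg.tooth_sets)
        if cfg.tooth_sets
        else default_tooth_sets()
    )
    ranked = rank_candidates(
        cohort, outcomes, tooth_sets, _structures(cfg), _weightings(cfg)
    )

    # 3. best model
    best_row = ranked.iloc[0]
    best_teeth = tuple(int(t) for t in best_row["teeth"].split("+"))
    responses = build_response(cohort, best_row["outcome"], best_teeth)
    best = select_structure(
        responses,
        _structures(cfg),
        _weightings(cfg),
        outcome=best_row["outcome"],
        tooth_set=best_teeth,
    )

    # 4. posteriors for hypothetical observations
    hypo = hypothetical_observations(
        responses["response"].to_numpy(), cfg.n_hypothetical
    )
    predictions = []
    for sex in best.sexes:
        for y in hypo:
            post = posterior_age(
                float(y), sex, best, prior, cfg.grid_step, cfg.threshold_age
            )
            predictions.append(
                {
                    "sex": sex,
                    "observed": float(y),
                    "p_over": post.p_over,
                    "posterior_mean": post.mean(),
                }
            )

    report = {
        "schema_version": 1,
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": config_hash(cfg.model_dump(mode="json")),
        "screen": screen.to_dict(),
        "ranked": ranked.to_dict(orient="records"),
        "best_model": best.to_dict(),
        "predictions": predictions,
    }

    # 5. optional two-tooth combination
    if cfg.combine_teeth:
        teeth_a, teeth_b = (tuple(int(t) for t in ts) for ts in cfg.combine_teeth)
        spec = {}
        for key, teeth in (("a", teeth_a), ("b", teeth_b)):
            resp = build_response(cohort, best_row["outcome"], teeth)
            m = select_structure(
                resp,
                tuple(s for s in _structures(cfg) if s != "v"),
                _weightings(cfg),
            )
            spec[key] = MarginalSpec(
                best_row["outcome"], teeth, m.structure, m.weighting
            )
        bfit = fit_bivariate(cohort, spec["a"], spec["b"])
        combined = []
        for sex in bfit.model_a.sexes:
            for y in hypo:
                post = posterior_age_combined(
                    float(y), float(y), sex, bfit, prior,
                    cfg.grid_step, cfg.threshold_age,
                )
                combined.append(
                    {
                        "sex": sex,
                        "observed": float(y),
                        "p_over": post.p_over,
                        "p_over_a": post.extras["p_over_a"],
                        "p_over_b": post.extras["p_over_b"],
                    }
                )
        report["combination"] = {
            "fit": bfit.to_dict(),
            "predictions": combined,
        }
    return report
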