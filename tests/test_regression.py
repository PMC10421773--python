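import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from molarage import SyntheticConfig, generate_cohort
from molarage.regression import (
    SEX_STRUCTURES,
    VARIANCE_WEIGHTINGS,
    FittedModel,
    ModelError,
    build_response,
    fit_wls,
    rank_candidates,
    select_structure,
    variance_multiplier,
)


def _make_responses(rng, n, structure_params, weighting="constant", sigma=0.2):
    age = rng.uniform(14, 24, n)
    sex = rng.choice(["F", "M"], n)
    b0f, b0m, b1f, b1m = structure_params
    mu = np.where(sex == "M", b0m + b1m * age, b0f + b1f * age)
    sd = sigma * np.sqrt(variance_multiplier(weighting, age))
    return pd.DataFrame(
        {"sex": sex, "age": age, "response": mu + rng.normal(0, 1, n) * sd}
    )


class TestBuildResponse:
    def test_single_tooth_equals_log_outcome(self, large_cohort):
        from molarage.transforms import log_outcome_matrix

        resp = build_response(large_cohort, "4a", (47,))
        sub = large_cohort[large_cohort["tooth_fdi"] == 47]
        logs = log_outcome_matrix(sub, ("4a",))["4a"].to_numpy()
        merged = sub.assign(expected=logs).merge(
            resp, on="participant_id", suffixes=("", "_r")
        )
        assert np.allclose(merged["expected"], merged["response"])

    def test_mean_of_two_teeth(self):
        # outcomes e^-2 and e^-3 -> mean log response -2.5
        vol = lambda soft: {"hsst_ml": soft / 2, "lsst_ml": soft / 2}
        rows = []
        for tooth, log4a in ((16, -2.0), (26, -3.0)):
            frac = np.exp(log4a)
            total = 1.2
            rows.append(
                {
                    "participant_id": "P1",
                    "sex": "F",
                    "age_years": 18.0,
                    "tooth_fdi": tooth,
                    "hard_ml": total * (1 - frac),
                    **{k: v * total for k, v in vol(frac).items()},
                }
            )
        resp = build_response(pd.DataFrame(rows), "4a", (16, 26))
        assert resp["response"].iloc[0] == pytest.approx(-2.5, rel=1e-12)

    def test_identical_teeth_mean_equals_either(self):
        row = {
            "participant_id": "P1",
            "sex": "M",
            "age_years": 20.0,
            "hard_ml": 1.1,
            "hsst_ml": 0.07,
            "lsst_ml": 0.028,
        }
        cohort = pd.DataFrame([{**row, "tooth_fdi": 16}, {**row, "tooth_fdi": 26}])
        resp = build_response(cohort, "4a", (16, 26))
        assert resp["response"].iloc[0] == pytest.approx(np.log(0.098 / 1.198))

    def test_replica_counts(self, replica_cohort):
        # single-tooth n equals the printed per-tooth counts
        resp = build_response(replica_cohort, "4a", (47,))
        assert (resp["sex"] == "M").sum() == 29
        assert (resp["sex"] == "F").sum() == 56

    def test_no_observations(self, large_cohort):
        with pytest.raises(ModelError, match="no usable observations"):
            build_response(large_cohort[large_cohort["tooth_fdi"] == 16], "4a", (47,))

    def test_empty_tooth_set(self, large_cohort):
        with pytest.raises(ValueError, match="non-empty"):
            build_response(large_cohort, "4a", ())


class TestFitWLS:
    def test_exact_interpolation_two_points(self):
        df = pd.DataFrame(
            {"sex": ["M", "M"], "age": [14.0, 23.0], "response": [0.0, 9.0]}
        )
        fit = fit_wls(df, "i", "constant")
        assert fit.params == pytest.approx([-14.0, 1.0], abs=1e-10)
        assert fit.sigma2_ml == pytest.approx(0.0, abs=1e-20)

    def test_matches_statsmodels_ols(self, tiny_responses):
        sm = pytest.importorskip("statsmodels.api")
        fit = fit_wls(tiny_responses, "i", "constant")
        X = sm.add_constant(tiny_responses["age"].to_numpy())
        res = sm.OLS(tiny_responses["response"].to_numpy(), X).fit()
        assert fit.params == pytest.approx(res.params, rel=1e-10)
        assert fit.loglik == pytest.approx(res.llf, rel=1e-10)
        assert fit.aic == pytest.approx(res.aic + 2.0, rel=1e-10)  # sm omits sigma in k
        assert fit.age_pvalues["M"] == pytest.approx(res.pvalues[1], rel=1e-10)

    @pytest.mark.parametrize("weighting", ["age", "inv_age"])
    def test_matches_statsmodels_wls(self, tiny_responses, weighting):
        sm = pytest.importorskip("statsmodels.api")
        fit = fit_wls(tiny_responses, "ii", weighting)
        age = tiny_responses["age"].to_numpy()
        male = (tiny_responses["sex"] == "M").astype(float).to_numpy()
        X = np.column_stack([np.ones_like(age), male, age])
        w = 1.0 / variance_multiplier(weighting, age)
        res = sm.WLS(tiny_responses["response"].to_numpy(), X, weights=w).fit()
        assert fit.params == pytest.approx(res.params, rel=1e-10)
        assert fit.loglik == pytest.approx(res.llf, rel=1e-10)
        assert fit.s2 == pytest.approx(res.mse_resid, rel=1e-10)
        assert fit.age_pvalues["F"] == pytest.approx(res.pvalues[2], rel=1e-10)
        np.testing.assert_allclose(fit.cov, res.cov_params(), rtol=1e-9)

    def test_closed_form_equals_numeric_minimiser(self, tiny_responses):
        fit = fit_wls(tiny_responses, "iv", "inv_age")
        age = tiny_responses["age"].to_numpy()
        male = (tiny_responses["sex"] == "M").to_numpy().astype(float)
        female = 1 - male
        X = np.column_stack([female, male, age * female, age * male])
        w = 1.0 / variance_multiplier("inv_age", age)
        y = tiny_responses["response"].to_numpy()
        obj = lambda b: np.sum(w * (y - X @ b) ** 2)
        res = optimize.minimize(obj, np.zeros(4), method="Nelder-Mead",
                                options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 50000})
        assert fit.params == pytest.approx(res.x, abs=1e-6)
        assert obj(fit.params) <= res.fun + 1e-8

    def test_loglik_direct_density_oracle(self, tiny_responses):
        # brute-force sum of weighted Gaussian log densities
        fit = fit_wls(tiny_responses, "iii", "age")
        age = tiny_responses["age"].to_numpy()
        mu = np.array(
            [fit.predict_mean(a, s) for a, s in zip(age, tiny_responses["sex"])]
        )
        var = fit.sigma2_ml * variance_multiplier("age", age)
        direct = stats.norm.logpdf(
            tiny_responses["response"].to_numpy(), mu, np.sqrt(var)
        ).sum()
        assert fit.loglik == pytest.approx(direct, rel=1e-12)

    def test_aic_identity(self, tiny_responses):
        for s in SEX_STRUCTURES:
            for w in VARIANCE_WEIGHTINGS:
                fit = fit_wls(tiny_responses, s, w)
                assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.loglik, rel=1e-12)

    def test_constant_weighting_is_ols(self, tiny_responses):
        fit_c = fit_wls(tiny_responses, "i", "constant")
        y = tiny_responses["response"].to_numpy()
        age = tiny_responses["age"].to_numpy()
        slope, intercept = np.polyfit(age, y, 1)
        assert fit_c.params == pytest.approx([intercept, slope], rel=1e-10)

    def test_structure_iv_nests_ii_iii(self, tiny_responses):
        def wrss(fit):
            age = tiny_responses["age"].to_numpy()
            mu = np.array(
                [fit.predict_mean(a, s) for a, s in zip(age, tiny_responses["sex"])]
            )
            w = 1.0 / variance_multiplier(fit.weighting, age)
            return np.sum(w * (tiny_responses["response"].to_numpy() - mu) ** 2)

        rss = {s: wrss(fit_wls(tiny_responses, s, "inv_age")) for s in ("ii", "iii", "iv")}
        assert rss["iv"] <= rss["ii"] + 1e-12
        assert rss["iv"] <= rss["iii"] + 1e-12

    def test_structure_v_separate_scales(self, tiny_responses):
        fit = fit_wls(tiny_responses, "v", "constant")
        assert set(fit.submodels) == {"F", "M"}
        s_f = fit_wls(tiny_responses[tiny_responses["sex"] == "F"], "i", "constant")
        assert fit.submodels["F"].params == pytest.approx(s_f.params, rel=1e-12)
        assert fit.loglik == pytest.approx(
            fit.submodels["F"].loglik + fit.submodels["M"].loglik, rel=1e-12
        )
        assert fit.aic == pytest.approx(
            fit.submodels["F"].aic + fit.submodels["M"].aic, rel=1e-12
        )
        assert fit.k == 6

    def test_per_sex_pvalue_keys(self, tiny_responses):
        for s in ("iii", "iv", "v"):
            fit = fit_wls(tiny_responses, s, "constant")
            assert set(fit.age_pvalues) == {"F", "M"}
        for s in ("i", "ii"):
            fit = fit_wls(tiny_responses, s, "constant")
            assert fit.age_pvalues["F"] == fit.age_pvalues["M"]

    def test_one_sex_absent_raises_named_error(self, tiny_responses):
        males = tiny_responses[tiny_responses["sex"] == "M"]
        with pytest.raises(ModelError, match="structure iv"):
            fit_wls(males, "iv", "constant")

    def test_nonpositive_age_rejected(self):
        df = pd.DataFrame({"sex": ["M"] * 3, "age": [0.0, 1, 2], "response": [0.0, 1, 2]})
        with pytest.raises(ModelError, match="positive"):
            fit_wls(df, "i", "age")

    def test_parameter_recovery_structure_iii(self):
        # generate under (iii, inv_age) and recover within 3 SE at n=500
        rng = np.random.default_rng(5)
        n = 500
        age = rng.uniform(14, 24, n)
        sex = rng.choice(["F", "M"], n)
        b0, b1f, b1m = -1.6, -0.06, -0.04
        slope = np.where(sex == "M", b1m, b1f)
        sd = 1.0 * np.sqrt(variance_multiplier("inv_age", age))
        y = b0 + slope * age + rng.normal(0, 1, n) * sd
        fit = fit_wls(pd.DataFrame({"sex": sex, "age": age, "response": y}), "iii", "inv_age")
        se = np.sqrt(np.diag(fit.cov))
        for est, truth, s in zip(fit.params, (b0, b1f, b1m), se):
            assert abs(est - truth) < 3 * s

    def test_serialisation_roundtrip(self, tiny_responses):
        for s in ("ii", "v"):
            fit = fit_wls(tiny_responses, s, "inv_age", outcome="4a", tooth_set=(47,))
            back = FittedModel.from_dict(fit.to_dict())
            assert back.predict_mean(19.3, "F") == pytest.approx(
                fit.predict_mean(19.3, "F"), rel=1e-14
            )
            assert back.predict_var(19.3, "M") == pytest.approx(
                fit.predict_var(19.3, "M"), rel=1e-14
            )
            assert back.aic == pytest.approx(fit.aic, rel=1e-15)

    def test_type_one_error_near_nominal(self):
        # under no age effect, the age t-test rejects at ~5%
        rng = np.random.default_rng(0)
        reps, n, rej = 2000, 50, 0
        for _ in range(reps):
            df = pd.DataFrame(
                {
                    "sex": ["M"] * n,
                    "age": rng.uniform(14, 24, n),
                    "response": rng.normal(0, 1, n),
                }
            )
            rej += fit_wls(df, "i", "constant").age_pvalues["M"] < 0.05
        mc_se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rej / reps - 0.05) < 2 * mc_se + 1e-9


class TestSelectStructure:
    def test_single_cell_restriction(self, tiny_responses):
        best = select_structure(tiny_responses, structures=("ii",), weightings=("age",))
        assert (best.structure, best.weighting) == ("ii", "age")

    def test_duplicated_sex_data_prefers_no_sex_terms(self):
        rng = np.random.default_rng(3)
        n = 120
        age = rng.uniform(14, 24, n)
        y = -1.5 - 0.05 * age + rng.normal(0, 0.2, n)
        df = pd.DataFrame(
            {
                "sex": ["F"] * n + ["M"] * n,
                "age": np.concatenate([age, age]),
                "response": np.concatenate([y, y]),
            }
        )
        best = select_structure(df, weightings=("constant",))
        assert best.structure == "i"

    def test_generating_structure_selected_large_n(self):
        rng = np.random.default_rng(17)
        df = _make_responses(
            rng, 3000, (-1.0, -2.4, -0.09, -0.03), weighting="inv_age", sigma=1.2
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            best = select_structure(df)
        assert best.structure in ("iv", "v")
        assert best.weighting == "inv_age"

    def test_tie_breaks_toward_fewer_parameters(self, tiny_responses):
        a = fit_wls(tiny_responses, "ii", "constant")
        b = fit_wls(tiny_responses, "iv", "constant")
        # force an artificial tie by restricting to one cell twice
        best = select_structure(tiny_responses, structures=("ii", "iv"),
                                weightings=("constant",))
        assert best.aic == pytest.approx(min(a.aic, b.aic))

    def test_no_fittable_cell(self):
        df = pd.DataFrame({"sex": ["M"], "age": [18.0], "response": [0.0]})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with pytest.raises(ModelError, match="no fittable cell"):
                select_structure(df, structures=("iv",))


class TestRankCandidates:
    def test_single_candidate_rank_one(self, large_cohort):
        table = rank_candidates(large_cohort, ["4a"], [(47,)])
        assert len(table) == 1 and table["rank"].iloc[0] == 1

    def test_constructed_strongest_signal_ranks_first(self, large_cohort):
        # 4a carries the configured age trend; "1" (total) does not
        table = rank_candidates(large_cohort, ["1", "4a"], [(47,)])
        assert table.iloc[0]["outcome"] == "4a"
        assert table.iloc[-1]["outcome"] == "1"

    def test_noise_outcome_ranks_last(self, large_cohort):
        table = rank_candidates(large_cohort, ["4a", "1"], [(47,), (46,)])
        assert table.iloc[0]["outcome"] == "4a"
        assert set(table.tail(2)["outcome"]) == {"1"}

    def test_empty_candidates_rejected(self, large_cohort):
        with pytest.raises(ValueError, match="at least one"):
            rank_candidates(large_cohort, [], [])
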