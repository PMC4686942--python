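"""Logistic adjustment ladder, ZIP severity model, categorization, onset."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit, gammaln

from vitdmr import (
    ModelSpec,
    categorize_vitd,
    category_table,
    default_config,
    early_onset_flag,
    fit_logistic_ladder,
    fit_zip_severity,
    generate_cohort,
    ladder,
)

from conftest import null_effects


class TestLadderStructure:
    def test_ladder_nesting_body_variant(self):
        specs = {s.tag: s for s in ladder("body")}
        assert specs["unadjusted"].covariates == () and not specs["unadjusted"].season
        assert specs["m1"].season and specs["m1"].covariates == ()
        assert specs["m2"].covariates == ("lag_months",)
        assert specs["m3"].covariates == ("sex", "age_at_measure")
        assert set(specs["m4"].covariates) == {"sex", "age_at_measure", "maternal_education"}
        assert set(specs["m5"].covariates) == {"sex", "age_at_measure", "bmi"}

    def test_footnote_variant_keeps_lag_in_m3(self):
        specs = {s.tag: s for s in ladder("footnote")}
        assert "lag_months" in specs["m3"].covariates

    def test_unknown_covariate_rejected(self):
        with pytest.raises(ValueError, match="unknown covariates"):
            ModelSpec("bad", covariates=("shoe_size",))


class TestLogisticLadder:
    def test_null_generator_or_near_one(self):
        config = default_config(
            n=30_000, seed=40, causal_log_or_per_nmol=0.0,
            confounder_effects=null_effects(), missing_rates={},
        )
        cohort = generate_cohort(config)
        est = fit_logistic_ladder(cohort, "caries", [ModelSpec("unadjusted")])[0]
        assert 0.97 <= est.or_per_10 <= 1.03

    def test_recovers_simulated_causal_or(self):
        config = default_config(
            n=30_000, seed=41, causal_log_or_per_nmol=np.log(0.80) / 10,
            confounder_effects=null_effects(), missing_rates={},
        )
        cohort = generate_cohort(config)
        est = fit_logistic_ladder(cohort, "caries", [ModelSpec("unadjusted")])[0]
        se10 = (np.log(est.ci_high) - np.log(est.or_per_10)) / 1.959964
        assert abs(np.log(est.or_per_10) - np.log(0.80)) < 3 * se10

    def test_complete_case_n_non_increasing_along_ladder(self, default_cohort):
        cohort = default_cohort.copy()
        rng = np.random.default_rng(42)
        cohort.loc[rng.random(len(cohort)) < 0.1, "bmi"] = np.nan
        cohort.loc[rng.random(len(cohort)) < 0.1, "lag_months"] = np.nan
        ests = fit_logistic_ladder(cohort, "caries")
        assert ests[0].n_used >= ests[2].n_used
        assert ests[0].n_used >= ests[-1].n_used

    def test_or_ci_ordering_and_per10_scaling(self, default_cohort):
        for est in fit_logistic_ladder(default_cohort, "caries"):
            assert 0 < est.ci_low <= est.or_per_10 <= est.ci_high

    def test_single_class_outcome_rejected(self, default_cohort):
        cohort = default_cohort.copy()
        cohort["caries"] = 1.0
        with pytest.raises(ValueError, match="single class"):
            fit_logistic_ladder(cohort, "caries", [ModelSpec("unadjusted")])

    def test_matches_direct_likelihood_oracle(self, logistic_fixture):
        # independent oracle: BFGS on the log-likelihood with analytic gradient
        df = logistic_fixture
        cohort = pd.DataFrame(
            {
                "vitd": df["x"],
                "caries": df["y"],
                "age_at_measure": df["z"] * 10 + 117,
                "sample_date": pd.Timestamp("2001-06-01"),
            }
        )
        est = fit_logistic_ladder(
            cohort, "caries", [ModelSpec("custom", covariates=("age_at_measure",))]
        )[0]
        A = np.column_stack([np.ones(len(df)), df["x"], cohort["age_at_measure"]])
        y = df["y"].to_numpy()

        def nll(b):
            lp = A @ b
            return -np.sum(y * lp - np.logaddexp(0, lp))

        def grad(b):
            return -(A.T @ (y - expit(A @ b)))

        opt = minimize(nll, np.zeros(3), jac=grad, method="BFGS",
                       options={"gtol": 1e-10})
        assert np.log(est.or_per_10) / 10 == pytest.approx(opt.x[1], abs=1e-6)


class TestCategorizeVitd:
    @pytest.mark.parametrize(
        "value, expected",
        [
            (0.0, "deficient"),
            (29.99, "deficient"),
            (30.0, "insufficient"),
            (49.99, "insufficient"),
            (50.0, "sufficient"),
            (60.9, "sufficient"),
        ],
    )
    def test_half_open_boundaries(self, value, expected):
        assert categorize_vitd([value]).iloc[0] == expected

    def test_missing_propagates_and_negative_rejected(self):
        cats = categorize_vitd([np.nan, 60.0])
        assert pd.isna(cats.iloc[0]) and cats.iloc[1] == "sufficient"
        with pytest.raises(ValueError, match="negative"):
            categorize_vitd([-1.0])

    def test_configurable_boundaries(self):
        cats = categorize_vitd([40.0], boundaries=(25.0, 37.5))
        assert cats.iloc[0] == "sufficient"


class TestEarlyOnset:
    def test_exact_tertiles_one_to_nine(self):
        flags = early_onset_flag(pd.Series(np.arange(1.0, 10.0)))
        assert flags.tolist() == [1, 1, 1, 0, 0, 0, 0, 0, 0]

    def test_uniform_ages_flag_about_one_third(self):
        rng = np.random.default_rng(43)
        ages = pd.Series(rng.uniform(38, 91, 3_000))
        assert early_onset_flag(ages).mean() == pytest.approx(1 / 3, abs=0.04)

    def test_heavy_ties_inclusive_and_deterministic(self):
        # questionnaire-style tied ages: ties at the cut all flagged early
        ages = pd.Series([65.0] * 40 + [77.0] * 30 + [91.0] * 30)
        flags = early_onset_flag(ages)
        assert flags[:40].eq(1).all() and flags[40:].eq(0).all()
        assert flags.equals(early_onset_flag(ages))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="tertile undefined"):
            early_onset_flag(pd.Series([77.0] * 10))
        with pytest.raises(ValueError, match="at least 3"):
            early_onset_flag(pd.Series([65.0, 77.0]))


class TestZipSeverity:
    def test_collapses_to_poisson_without_inflation(self):
        config = default_config(
            n=6_000, seed=44, zip_inflation=0.0, clinical_fraction=1.0,
            missing_rates={},
        )
        cohort = generate_cohort(config)
        fit = fit_zip_severity(cohort["dmft"], cohort["vitd"])
        assert expit(fit.inflation_params["inflate_const"]) < 0.02
        plain = sm.Poisson(
            cohort["dmft"], sm.add_constant(cohort[["vitd"]])
        ).fit(disp=0)
        assert fit.count_params["vitd"] == pytest.approx(
            plain.params["vitd"], abs=plain.bse["vitd"]
        )

    def test_recovers_simulated_count_ratio(self):
        config = default_config(
            n=30_000, seed=45, clinical_fraction=1.0, missing_rates={},
            confounder_effects=null_effects(),
        )
        cohort = generate_cohort(config)
        fit = fit_zip_severity(cohort["dmft"], cohort["vitd"])
        se10 = (np.log(fit.ci_high) - np.log(fit.count_ratio_per_10)) / 1.959964
        assert abs(np.log(fit.count_ratio_per_10) - np.log(0.95)) < 3 * se10

    def test_matches_direct_likelihood_oracle(self, zip_fixture):
        df = zip_fixture
        fit = fit_zip_severity(df["dmft"], df["x"])
        W = np.column_stack([np.ones(len(df)), df["x"]])
        dm = df["dmft"].to_numpy()

        def nll(b):
            pi, lam = expit(b[0]), np.exp(W @ b[1:])
            ll = np.where(
                dm == 0,
                np.log(pi + (1 - pi) * np.exp(-lam)),
                np.log1p(-pi) - lam + dm * (W @ b[1:]) - gammaln(dm + 1),
            )
            return -np.sum(ll)

        def grad(b):
            pi, eta = expit(b[0]), W @ b[1:]
            lam = np.exp(eta)
            zero = dm == 0
            denom = pi + (1 - pi) * np.exp(-lam)
            dg = np.where(zero, pi * (1 - pi) * (1 - np.exp(-lam)) / denom, -pi)
            deta = np.where(zero, -(1 - pi) * np.exp(-lam) / denom * lam, dm - lam)
            return -np.concatenate([[dg.sum()], W.T @ deta])

        opt = minimize(nll, np.zeros(3), jac=grad, method="BFGS",
                       options={"gtol": 1e-10})
        fitted = np.concatenate(
            [fit.inflation_params.to_numpy(), fit.count_params.to_numpy()]
        )
        assert np.max(np.abs(fitted - opt.x)) < 1e-6

    def test_fitted_optimum_beats_random_perturbations(self, zip_fixture):
        df = zip_fixture
        fit = fit_zip_severity(df["dmft"], df["x"])
        W = np.column_stack([np.ones(len(df)), df["x"]])
        dm = df["dmft"].to_numpy()

        def ll(b):
            pi, lam = expit(b[0]), np.exp(W @ b[1:])
            return np.sum(
                np.where(
                    dm == 0,
                    np.log(pi + (1 - pi) * np.exp(-lam)),
                    np.log1p(-pi) - lam + dm * (W @ b[1:]) - gammaln(dm + 1),
                )
            )

        best = np.concatenate(
            [fit.inflation_params.to_numpy(), fit.count_params.to_numpy()]
        )
        ll_best = ll(best)
        rng = np.random.default_rng(46)
        for _ in range(1_000):
            assert ll(best + rng.normal(0, 0.1, size=3)) <= ll_best + 1e-9

    def test_non_integer_dmft_rejected(self):
        with pytest.raises(ValueError, match="non-negative integers"):
            fit_zip_severity(pd.Series([0.0, 1.5, 2.0]), pd.Series([50.0, 60.0, 70.0]))


class TestCategoryTable:
    def test_counts_partition_non_missing(self, default_cohort):
        result = category_table(default_cohort)
        complete = default_cohort.dropna(subset=["vitd", "caries"])
        assert result.table["n"].sum() == len(complete)

    def test_single_category_test_undefined(self):
        cohort = pd.DataFrame({"vitd": [60.0, 70.0, 80.0], "caries": [0.0, 1.0, 0.0]})
        result = category_table(cohort)
        assert np.isnan(result.chi2)
        assert result.table.loc[result.table["category"] == "deficient", "n"].iloc[0] == 0

    def test_null_chi_square_p_values_roughly_uniform(self):
        # caries independent of category: KS check on repeated seeds
        pvals = []
        rng = np.random.default_rng(47)
        for _ in range(300):
            n = 3_000
            cohort = pd.DataFrame(
                {
                    "vitd": rng.gamma(9.0, 7.0, n),
                    "caries": (rng.random(n) < 0.3).astype(float),
                }
            )
            pvals.append(category_table(cohort).p_value)
        from scipy import stats

        assert stats.kstest(pvals, "uniform").pvalue > 0.01
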