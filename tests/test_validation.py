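"""Misclassification cross-tabulation, t-test, quintiles, balance tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vitdmr import (
    balance_tests,
    cross_tabulate,
    default_config,
    generate_cohort,
    misclassification_ttest,
    prevalence,
    quintile_assign,
    weighted_risk_score,
)
from vitdmr.synthetic_cohort import DEFAULT_SNPS, DOSAGE_PREFIX

from conftest import null_effects

BALANCE_KINDS = {
    "sex": "categorical",
    "maternal_education": "categorical",
    "age_at_measure": "continuous",
    "bmi": "continuous",
    "lag_months": "continuous",
}


def _flags_from_counts(n00, n10, n01, n11):
    """clinical, questionnaire vectors realising a 2x2 count table."""
    clinical = np.array([0] * n00 + [1] * n10 + [0] * n01 + [1] * n11, dtype=float)
    questionnaire = np.array([0] * (n00 + n10) + [1] * (n01 + n11), dtype=float)
    return clinical, questionnaire


class TestCrossTabulate:
    def test_validation_sample_misclassification_rates(self):
        # 474/72 questionnaire controls, 5/73 questionnaire cases
        clinical, questionnaire = _flags_from_counts(474, 72, 5, 73)
        tab = cross_tabulate(clinical, questionnaire)
        assert tab.fp_rate == pytest.approx(5 / 78, abs=1e-12)
        assert tab.fn_rate == pytest.approx(72 / 546, abs=1e-12)
        assert round(100 * tab.fp_rate) == 6
        assert round(100 * tab.fn_rate) == 13
        assert tab.total == 624

    def test_margins_reproduce_input_prevalences(self):
        rng = np.random.default_rng(60)
        clinical = (rng.random(500) < 0.25).astype(float)
        questionnaire = (rng.random(500) < 0.15).astype(float)
        tab = cross_tabulate(clinical, questionnaire)
        assert tab.counts.loc["caries", "total"] == clinical.sum()
        assert tab.counts.loc["total", "caries"] == questionnaire.sum()

    def test_identical_flags_perfect_agreement(self):
        flags = np.array([0, 1, 1, 0, 1], dtype=float)
        tab = cross_tabulate(flags, flags)
        assert tab.fp_rate == 0.0 and tab.fn_rate == 0.0

    def test_swapping_flag_vectors_transposes_table(self):
        clinical, questionnaire = _flags_from_counts(40, 7, 3, 10)
        a = cross_tabulate(clinical, questionnaire).counts
        b = cross_tabulate(questionnaire, clinical).counts
        assert np.array_equal(
            a.loc[["no caries", "caries"], ["no caries", "caries"]].to_numpy(),
            b.loc[["no caries", "caries"], ["no caries", "caries"]].to_numpy().T,
        )

    def test_zero_questionnaire_cases_fp_undefined(self):
        tab = cross_tabulate([0.0, 1.0, 0.0], [0.0, 0.0, 0.0])
        assert np.isnan(tab.fp_rate)

    def test_per_cell_exposure_medians(self):
        clinical = np.array([0.0, 0.0, 1.0, 1.0])
        questionnaire = np.array([0.0, 1.0, 0.0, 1.0])
        vitd = np.array([60.0, 55.0, 70.0, 40.0])
        tab = cross_tabulate(clinical, questionnaire, vitd)
        cell = tab.vitd_summary.query(
            "clinical == 'caries' and questionnaire == 'no caries'"
        )
        assert cell["median"].iloc[0] == 70.0


class TestMisclassificationTtest:
    def test_matches_hand_computed_pooled_t(self):
        # six observations, two groups of three
        vitd = np.array([60.0, 62.0, 64.0, 58.0, 57.0, 59.0])
        correct = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        t, p = misclassification_ttest(vitd, correct)
        m1, m2 = 62.0, 58.0
        s2 = (sum((np.array([60, 62, 64]) - m1) ** 2) + sum((np.array([58, 57, 59]) - m2) ** 2)) / 4
        expected_t = (m1 - m2) / np.sqrt(s2 * (1 / 3 + 1 / 3))
        assert t == pytest.approx(expected_t, abs=1e-10)
        assert p == pytest.approx(2 * stats.t.sf(expected_t, df=4), abs=1e-10)

    def test_exact_null_p_near_one(self):
        rng = np.random.default_rng(61)
        base = rng.normal(65, 20, 400)
        vitd = np.concatenate([base, base])  # identical distributions
        correct = np.concatenate([np.ones(400), np.zeros(400)])
        _, p = misclassification_ttest(vitd, correct)
        assert p > 0.99

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            misclassification_ttest([60.0, 61.0, 62.0], [1.0, 1.0, 0.0])


class TestQuintileAssign:
    def test_exact_split_one_to_ten(self):
        labels = quintile_assign(pd.Series(np.arange(1.0, 11.0)))
        assert labels.tolist() == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]

    def test_continuous_values_near_equal_groups(self):
        rng = np.random.default_rng(62)
        labels = quintile_assign(pd.Series(rng.normal(size=6_259)))
        sizes = labels.value_counts()
        assert sizes.max() - sizes.min() <= 2
        assert sizes.sum() == 6_259

    def test_discrete_ties_go_to_lower_quintile(self):
        values = pd.Series([1.0] * 30 + [2.0] * 10 + [3.0] * 10 + [4.0] * 50)
        labels = quintile_assign(values)
        # the value spanning the 20% cut is assigned entirely to quintile 1
        assert labels[values == 1.0].eq(1).all()
        # monotone in the values and deterministic
        assert (labels.groupby(values).first().diff().dropna() >= 0).all()
        assert labels.equals(quintile_assign(values))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(63)
        values = pd.Series(rng.normal(size=500))
        perm = rng.permutation(500)
        direct = quintile_assign(values).to_numpy()
        permuted = quintile_assign(values.iloc[perm].reset_index(drop=True)).to_numpy()
        assert np.array_equal(direct[perm], permuted)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            quintile_assign(pd.Series([5.0] * 100))


class TestBalanceTests:
    def test_identical_confounder_gives_f_zero_p_one(self):
        cohort = pd.DataFrame({"bmi": [17.0] * 100})
        quintiles = pd.Series(np.repeat([1, 2, 3, 4, 5], 20), dtype=float)
        table = balance_tests(cohort, quintiles, {"bmi": "continuous"})
        row = table.tests.iloc[0]
        assert row["statistic"] == 0.0 and row["p_value"] == 1.0

    def test_chi_square_matches_hand_arithmetic(self):
        # hand-built 2x5 table
        counts = np.array([[10, 20, 30, 20, 20], [30, 20, 10, 20, 20]])
        sex = np.repeat(["female", "male"], counts.sum(axis=1))
        q = np.concatenate([np.repeat([1, 2, 3, 4, 5], row) for row in counts])
        cohort = pd.DataFrame({"sex": sex})
        table = balance_tests(cohort, pd.Series(q, dtype=float), {"sex": "categorical"})
        expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / counts.sum()
        manual = ((counts - expected) ** 2 / expected).sum()
        assert table.tests.iloc[0]["statistic"] == pytest.approx(manual, abs=1e-10)

    def test_null_confounder_p_roughly_uniform(self):
        rng = np.random.default_rng(64)
        pvals = []
        for _ in range(200):
            cohort = pd.DataFrame({"bmi": rng.normal(17, 2, 1_000)})
            quintiles = quintile_assign(pd.Series(rng.normal(size=1_000)))
            pvals.append(
                balance_tests(cohort, quintiles, {"bmi": "continuous"}).tests.iloc[0]["p_value"]
            )
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_score_quintiles_balanced_exposure_quintiles_not(self):
        # genotype independent of confounders; exposure correlated with them
        flagged = 0
        for seed in range(3):
            cohort = generate_cohort(default_config(n=6_000, seed=70 + seed, missing_rates={}))
            score = weighted_risk_score(
                cohort[[DOSAGE_PREFIX + s.id for s in DEFAULT_SNPS]],
                [s.weight for s in DEFAULT_SNPS],
            )
            score_balance = balance_tests(
                cohort, quintile_assign(score.values), BALANCE_KINDS
            )
            assert (score_balance.tests["p_value"] > 0.001).all()
            vitd_balance = balance_tests(
                cohort, quintile_assign(cohort["vitd"]), BALANCE_KINDS
            )
            flagged += int((vitd_balance.tests["p_value"] < 0.001).any())
        assert flagged == 3  # built-in exposure-confounder correlations detected

    def test_quintile_ns_sum_to_analysis_n(self, default_cohort):
        quintiles = quintile_assign(default_cohort["vitd"])
        table = balance_tests(default_cohort, quintiles, {"bmi": "continuous"})
        assert table.n_per_quintile.sum() == default_cohort["vitd"].notna().sum()


class TestPrevalence:
    def test_study_count_arithmetic(self):
        assert prevalence(3_839, 14_043) == pytest.approx(27.3, abs=0.05)
        assert prevalence(716, 7_045) == pytest.approx(10.2, abs=0.05)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            prevalence(5, 0)
        with pytest.raises(ValueError):
            prevalence(10, 5)
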