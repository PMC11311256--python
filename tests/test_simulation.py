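"""Synthetic cohorts and microsimulation: determinism, calibration, recovery."""

import math
from decimal import Decimal

import numpy as np
import pytest

from tertbayes import (
    Category,
    CostConfig,
    LesionReclassifier,
    LikelihoodSet,
    SimParams,
    microsimulate,
    simulate_cohort,
)
from tertbayes.simulation import DEFAULT_ASSAY_FAILURE_RATE, DEFAULT_CATEGORY_COUNTS


def expected_savings_per_cohort(params: SimParams, config: CostConfig) -> float:
    """Closed-form expectation of scenario savings under the generative model.

    Derived by the law of total expectation over (category, truth, result):
    each conclusively tested lesion saves (re-excision - test) unless it
    remains in the ambiguous band, which under the default thresholds
    happens exactly for wild-type ambiguous-category lesions.
    """
    c_re = float(config.cost_reexcision)
    c_test = float(config.cost_tert_test)
    lk = params.likelihoods
    conclusive = 1.0 - params.assay_failure_rate
    p_uncertain = sum(
        params.category_mix.get(c, 0.0)
        for c in (Category.LIKELY_BENIGN, Category.AMBIGUOUS, Category.LIKELY_MALIGNANT)
    )
    p_amb = params.category_mix.get(Category.AMBIGUOUS, 0.0)
    pi_amb = params.true_rate(Category.AMBIGUOUS)
    p_wt_given_amb = pi_amb * lk.p_neg_given_mal + (1 - pi_amb) * lk.p_neg_given_ben
    per_lesion = conclusive * (
        p_uncertain * (c_re - c_test) - p_amb * p_wt_given_amb * c_re
    )
    return params.n_lesions * per_lesion


class TestSimulateCohort:
    def test_seed_determinism_byte_identical(self):
        params = SimParams(n_lesions=500, seed=42)
        a = simulate_cohort(params).to_csv(index=False)
        b = simulate_cohort(params).to_csv(index=False)
        assert a == b

    def test_different_seeds_differ(self):
        a = simulate_cohort(SimParams(n_lesions=500, seed=1))
        b = simulate_cohort(SimParams(n_lesions=500, seed=2))
        assert not a.equals(b)

    def test_total_failure_rate_makes_every_uncertain_lesion_inconclusive(self):
        cohort = simulate_cohort(SimParams(n_lesions=400, assay_failure_rate=1.0, seed=3))
        uncertain = cohort["preliminary_category"].isin(
            ["likely_benign", "ambiguous", "likely_malignant"]
        )
        assert (cohort.loc[uncertain, "tertp_status"] == "inconclusive").all()
        assert cohort.loc[~uncertain, "tertp_status"].isna().all()

    def test_mutation_rate_matches_generative_parameter(self):
        """Among truly malignant, conclusively tested lesions the mutated
        fraction is binomial around P(+|malignant)."""
        params = SimParams(n_lesions=20_000, seed=7)
        cohort = simulate_cohort(params)
        tested = cohort["tertp_status"].isin(["mutated", "wildtype"])
        mal = tested & (cohort["true_state"] == "malignant")
        frac = (cohort.loc[mal, "tertp_status"] == "mutated").mean()
        n = int(mal.sum())
        p = params.likelihoods.p_pos_given_mal
        assert abs(frac - p) <= 3 * math.sqrt(p * (1 - p) / n)

    def test_marginal_mutated_fraction_in_pure_ambiguous_mix(self):
        """Degenerate mix on ambiguous, prior 0.5: total mutated probability is
        0.5*0.41 + 0.5*0.014 = 0.212 by the law of total probability."""
        params = SimParams(
            n_lesions=2000, category_mix={Category.AMBIGUOUS: 1.0}, seed=11
        )
        cohort = simulate_cohort(params)
        conclusive = cohort[cohort["tertp_status"].isin(["mutated", "wildtype"])]
        frac = (conclusive["tertp_status"] == "mutated").mean()
        expected = 0.5 * 0.41 + 0.5 * 0.014
        se = math.sqrt(expected * (1 - expected) / len(conclusive))
        assert abs(frac - expected) <= 3 * se

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SimParams(n_lesions=0)
        with pytest.raises(ValueError, match="sum to 1"):
            SimParams(category_mix={Category.AMBIGUOUS: 0.7})
        with pytest.raises(ValueError):
            SimParams(assay_failure_rate=1.5)


class TestParameterRecovery:
    def test_likelihood_and_failure_rate_recovered_at_large_n(self):
        params = SimParams(n_lesions=50_000, seed=19)
        cohort = simulate_cohort(params)
        uncertain = cohort["preliminary_category"].isin(
            ["likely_benign", "ambiguous", "likely_malignant"]
        )
        n_unc = int(uncertain.sum())
        fail_hat = (cohort.loc[uncertain, "tertp_status"] == "inconclusive").mean()
        r = params.assay_failure_rate
        assert abs(fail_hat - r) <= 3 * math.sqrt(r * (1 - r) / n_unc)

        tested_mal = (
            uncertain
            & cohort["tertp_status"].isin(["mutated", "wildtype"])
            & (cohort["true_state"] == "malignant")
        )
        m = int(tested_mal.sum())
        s_hat = (cohort.loc[tested_mal, "tertp_status"] == "mutated").mean()
        s = params.likelihoods.p_pos_given_mal
        assert abs(s_hat - s) <= 3 * math.sqrt(s * (1 - s) / m)


class TestCalibration:
    def test_posteriors_calibrated_under_generative_model(self):
        """Per final band, the empirical malignant fraction lies within three
        binomial standard errors of the mean posterior at n = 10,000."""
        params = SimParams(
            n_lesions=10_000, category_mix={Category.AMBIGUOUS: 1.0}, seed=23
        )
        cohort = simulate_cohort(params)
        results = LesionReclassifier(
            cohort, likelihoods=params.likelihoods, priors=params.priors
        ).fit()
        table = results.calibration_table()
        assert len(table) >= 2  # mutated -> malignant band, wildtype -> ambiguous
        for band, row in table.iterrows():
            p, n = row["mean_posterior"], row["n"]
            se = math.sqrt(p * (1 - p) / n)
            assert abs(row["malignant_fraction"] - p) <= 3 * se, band
        assert table.loc["malignant", "mean_posterior"] == pytest.approx(0.97, abs=0.005)

    def test_perfect_test_on_truly_benign_lesions(self):
        params = SimParams(
            n_lesions=500,
            category_mix={Category.AMBIGUOUS: 1.0},
            likelihoods=LikelihoodSet(1.0, 0.0, 0.0, 1.0),
            true_malignancy_rates={Category.AMBIGUOUS: 0.0},
            seed=29,
        )
        cohort = simulate_cohort(params)
        results = LesionReclassifier(cohort, likelihoods=params.likelihoods).fit()
        table = results.calibration_table()
        # all conclusive lesions are wild-type with posterior 0 -> benign band
        assert list(table.index) == ["benign"]
        assert table.loc["benign", "malignant_fraction"] == 0.0

    def test_uninformative_test_reproduces_the_prior(self):
        params = SimParams(
            n_lesions=4000,
            category_mix={Category.AMBIGUOUS: 1.0},
            likelihoods=LikelihoodSet(0.3, 0.7, 0.3, 0.7),
            seed=31,
        )
        cohort = simulate_cohort(params)
        results = LesionReclassifier(cohort, likelihoods=params.likelihoods).fit()
        table = results.calibration_table()
        assert list(table.index) == ["ambiguous"]  # posterior == prior == 0.5
        assert table.loc["ambiguous", "mean_posterior"] == pytest.approx(0.5)
        n = table.loc["ambiguous", "n"]
        assert abs(table.loc["ambiguous", "malignant_fraction"] - 0.5) <= 3 * math.sqrt(
            0.25 / n
        )


class TestMicrosimulate:
    def test_mean_savings_matches_closed_form(self):
        params = SimParams(seed=123)
        config = CostConfig()
        dist = microsimulate(params, n_reps=500, cost_config=config)
        expected = expected_savings_per_cohort(params, config)
        mc_se = float(np.std(dist.savings, ddof=1)) / math.sqrt(dist.n_reps)
        assert abs(dist.mean - expected) <= 3 * mc_se
        assert dist.mean > 0  # testing projects a saving under reference conditions

    def test_free_test_never_loses_money(self):
        dist = microsimulate(
            SimParams(seed=5),
            n_reps=50,
            cost_config=CostConfig(cost_tert_test=Decimal(0)),
        )
        assert (dist.savings >= 0).all()

    def test_single_replicate_deterministic(self):
        params = SimParams(seed=77)
        a = microsimulate(params, n_reps=1)
        b = microsimulate(params, n_reps=1)
        assert a.savings.tolist() == b.savings.tolist()

    def test_summary_and_frame(self):
        dist = microsimulate(SimParams(seed=9), n_reps=20)
        frame = dist.to_frame()
        assert list(frame.columns) == ["replicate", "savings"]
        assert len(frame) == 20
        lo, hi = dist.interval
        assert lo <= dist.mean <= hi
        assert "20 cohorts" in dist.summary()

    def test_invalid_reps_rejected(self):
        with pytest.raises(ValueError):
            microsimulate(SimParams(seed=1), n_reps=0)


def test_default_mix_matches_reference_series():
    total = sum(DEFAULT_CATEGORY_COUNTS.values())
    assert total == 367
    assert DEFAULT_CATEGORY_COUNTS[Category.AMBIGUOUS] == 87
    assert DEFAULT_ASSAY_FAILURE_RATE == pytest.approx(24 / 175)
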