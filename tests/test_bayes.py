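"""Bayesian posterior of malignancy and threshold-band classification."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from tertbayes import (
    Category,
    LikelihoodSet,
    PriorMap,
    ThresholdScheme,
    classify_posterior,
    management_group,
    posterior_grid,
    posterior_malignant,
    reclassify_lesion,
)
from tertbayes.bayes import ManagementGroup

from conftest import bayes_oracle

probs = st.floats(0.0, 1.0)
open_probs = st.floats(0.001, 0.999)


class TestPosterior:
    @pytest.mark.parametrize(
        "prior, status, expected",
        [
            (0.25, "mutated", 0.91),
            (0.50, "mutated", 0.97),
            (0.75, "mutated", 0.99),
            (0.25, "wildtype", 0.17),
            (0.50, "wildtype", 0.37),
            (0.75, "wildtype", 0.64),
        ],
    )
    def test_reference_grid_two_decimals(self, reference_likelihoods, prior, status, expected):
        post = posterior_malignant(prior, reference_likelihoods, status)
        assert round(post, 2) == expected

    def test_wildtype_at_prior_quarter(self, reference_likelihoods):
        post = posterior_malignant(0.25, reference_likelihoods, "wildtype")
        assert post == pytest.approx(0.16629, abs=5e-6)

    @given(prior=probs, s=probs, f=probs)
    def test_agrees_with_joint_enumeration_oracle(self, prior, s, f):
        lk = LikelihoodSet(s, 1 - s, f, 1 - f)
        for status, positive in (("mutated", True), ("wildtype", False)):
            try:
                expected = bayes_oracle(prior, s, f, positive)
            except ZeroDivisionError:
                with pytest.raises(ZeroDivisionError):
                    posterior_malignant(prior, lk, status)
                continue
            assert posterior_malignant(prior, lk, status) == pytest.approx(
                expected, abs=1e-12
            )

    def test_absorbing_priors(self, reference_likelihoods):
        assert posterior_malignant(0.0, reference_likelihoods, "mutated") == 0.0
        assert posterior_malignant(1.0, reference_likelihoods, "wildtype") == 1.0

    @given(p1=open_probs, p2=open_probs)
    def test_strictly_increasing_in_prior(self, reference_likelihoods, p1, p2):
        lo, hi = sorted((p1, p2))
        if lo == hi:
            return
        for status in ("mutated", "wildtype"):
            assert posterior_malignant(lo, reference_likelihoods, status) < posterior_malignant(
                hi, reference_likelihoods, status
            )

    @given(prior=probs, p=open_probs)
    def test_uninformative_test_returns_prior(self, prior, p):
        """Likelihood ratio 1 (same result probability in both states)
        leaves the prior unchanged."""
        lk = LikelihoodSet(p, 1 - p, p, 1 - p)
        for status in ("mutated", "wildtype"):
            assert posterior_malignant(prior, lk, status) == pytest.approx(prior, abs=1e-12)

    @given(prior=open_probs)
    def test_mutated_raises_and_wildtype_lowers_prior(self, reference_likelihoods, prior):
        up = posterior_malignant(prior, reference_likelihoods, "mutated")
        down = posterior_malignant(prior, reference_likelihoods, "wildtype")
        assert down < prior < up

    def test_degenerate_update_raises(self):
        lk = LikelihoodSet(1.0, 0.0, 0.0, 1.0)
        with pytest.raises(ZeroDivisionError, match="degenerate"):
            posterior_malignant(0.0, lk, "mutated")

    def test_inconclusive_has_no_posterior(self, reference_likelihoods):
        with pytest.raises(ValueError, match="inconclusive"):
            posterior_malignant(0.5, reference_likelihoods, "inconclusive")

    def test_grid_table_layout(self, reference_likelihoods):
        grid = posterior_grid(PriorMap(), reference_likelihoods)
        assert list(grid.columns) == [0.25, 0.5, 0.75]
        assert grid.round(2).loc["mutated"].tolist() == [0.91, 0.97, 0.99]
        assert grid.round(2).loc["wildtype"].tolist() == [0.17, 0.37, 0.64]


class TestClassifyPosterior:
    @pytest.mark.parametrize(
        "p, band",
        [
            (0.0, Category.BENIGN),
            (0.05, Category.BENIGN),
            (0.1, Category.LIKELY_BENIGN),    # benign band is [0, 0.1)
            (0.17, Category.LIKELY_BENIGN),
            (0.2, Category.AMBIGUOUS),        # ambiguous is closed [0.2, 0.5]
            (0.37, Category.AMBIGUOUS),
            (0.5, Category.AMBIGUOUS),
            (0.64, Category.LIKELY_MALIGNANT),
            (0.9, Category.LIKELY_MALIGNANT), # malignant needs strictly > 0.9
            (0.91, Category.MALIGNANT),
            (0.97, Category.MALIGNANT),
            (1.0, Category.MALIGNANT),
        ],
    )
    def test_band_boundaries(self, p, band):
        assert classify_posterior(p) is band

    @given(p=probs)
    def test_bands_partition_unit_interval(self, p):
        band = classify_posterior(p)
        assert band in Category
        # each p maps to exactly one band; group mapping is total too
        assert management_group(band) in ManagementGroup

    @pytest.mark.parametrize("p", [-0.01, 1.01])
    def test_out_of_range_rejected(self, p):
        with pytest.raises(ValueError):
            classify_posterior(p)

    def test_reordered_thresholds_rejected(self):
        with pytest.raises(ValueError, match="thresholds"):
            ThresholdScheme(benign_lt=0.3, likely_benign_lt=0.2)


class TestReclassifyLesion:
    def test_ambiguous_mutated_becomes_malignant(self, reference_likelihoods):
        res = reclassify_lesion("ambiguous", "mutated", lk=reference_likelihoods)
        assert round(res.posterior, 2) == 0.97
        assert res.final_category is Category.MALIGNANT
        assert res.final_group is ManagementGroup.MALIGNANT

    def test_likely_benign_wildtype_stays_likely_benign(self, reference_likelihoods):
        res = reclassify_lesion("likely_benign", "wildtype", lk=reference_likelihoods)
        assert round(res.posterior, 2) == 0.17
        assert res.final_category is Category.LIKELY_BENIGN

    def test_inconclusive_short_circuits_to_preliminary(self, reference_likelihoods):
        res = reclassify_lesion("likely_malignant", "inconclusive", lk=reference_likelihoods)
        assert res.inconclusive
        assert res.final_category is Category.LIKELY_MALIGNANT
        assert res.posterior == res.prior == 0.75

    @pytest.mark.parametrize("category", ["benign", "malignant"])
    def test_confident_diagnoses_are_not_tested(self, category):
        with pytest.raises(ValueError, match="not tested"):
            reclassify_lesion(category, "wildtype")

    def test_labels_case_insensitive(self, reference_likelihoods):
        res = reclassify_lesion("Likely Benign", "WILDTYPE", lk=reference_likelihoods)
        assert res.preliminary is Category.LIKELY_BENIGN

    def test_prior_map_validation(self):
        with pytest.raises(ValueError, match="strictly in"):
            PriorMap({"likely_benign": 0.0, "ambiguous": 0.5, "likely_malignant": 0.75})
        with pytest.raises(ValueError, match="missing priors"):
            PriorMap({"ambiguous": 0.5})
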