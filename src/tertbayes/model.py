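"""Cohort-level model: reclassify a lesion table and summarise the result.

:class:`LesionReclassifier` is the model object: it holds a lesion table
(one row per lesion with a preliminary histopathological category and a
TERTp status) together with the evidence (likelihoods), the category
priors, and the posterior band thresholds.  ``fit()`` performs the Bayesian
update for every testable lesion and returns a
:class:`ReclassificationResults` carrying the per-lesion posteriors, the
cross-tabulations, the management-group tallies, and — via
``cost_comparison()`` — the two-scenario micro-costing comparison.

Lesions whose preliminary diagnosis is already confidently benign or
malignant bypass the molecular work-up: they are carried through unchanged
and never counted in the tested denominators.  Lesions with an inconclusive
assay keep their preliminary category, flagged, and are likewise excluded
from tested denominators.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .bayes import (
    UNCERTAIN_CATEGORIES,
    Category,
    ManagementGroup,
    PriorMap,
    ThresholdScheme,
    classify_posterior,
    management_group,
    posterior_grid,
    posterior_malignant,
)
from .calling import Call
from .costing import CostConfig, ScenarioComparison, scenario_costs
from .evidence import LikelihoodSet

__all__ = ["LesionReclassifier", "ReclassificationResults"]

_BAND_ORDER = [c.value for c in Category]
_GROUP_ORDER = [g.value for g in ManagementGroup]
_STATUS_ORDER = [Call.MUTATED.value, Call.WILDTYPE.value, Call.INCONCLUSIVE.value]


class LesionReclassifier:
    """Bayesian reclassification model for a cohort of melanocytic lesions.

    Parameters
    ----------
    data
        Lesion table with columns ``preliminary_category`` and
        ``tertp_status`` (``mutated`` / ``wildtype`` / ``inconclusive``);
        an optional ``lesion_id`` column and, for simulated cohorts, a
        ``true_state`` column (``malignant`` / ``benign``) are carried
        through.  Use :func:`tertbayes.io.load_lesion_table` to build the
        table from raw droplet counts.
    likelihoods, priors, thresholds
        Evidence and decision parameters; defaults are the package's
        reference values (0.41/0.59 vs 0.014/0.986; priors 0.25/0.5/0.75;
        bands cut at 0.1/0.2/0.5/0.9).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        likelihoods: Optional[LikelihoodSet] = None,
        priors: Optional[PriorMap] = None,
        thresholds: Optional[ThresholdScheme] = None,
    ):
        required = {"preliminary_category", "tertp_status"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"lesion table lacks required columns {sorted(missing)}")
        frame = data.copy(deep=True)
        frame["preliminary_category"] = [
            Category.parse(c).value for c in frame["preliminary_category"]
        ]
        frame["tertp_status"] = [
            None if (s is None or (isinstance(s, float) and np.isnan(s)) or str(s).strip() == "")
            else Call(str(s).strip().lower()).value
            for s in frame["tertp_status"]
        ]
        uncertain = frame["preliminary_category"].isin(
            [c.value for c in UNCERTAIN_CATEGORIES]
        )
        no_status = frame["tertp_status"].isna()
        if (uncertain & no_status).any():
            idx = list(frame.index[uncertain & no_status][:5])
            raise ValueError(f"rows {idx}: uncertain lesions lack a TERTp status")
        # A confident benign/malignant diagnosis is never tested; a recorded
        # assay result on such a row signals a mislabelled table.
        bad = ~uncertain & frame["tertp_status"].isin(
            [Call.MUTATED.value, Call.WILDTYPE.value]
        )
        if bad.any():
            idx = list(frame.index[bad][:5])
            raise ValueError(
                f"rows {idx}: lesions preliminarily classified benign/malignant "
                "must not carry a TERTp test result"
            )
        self.data = frame
        self.likelihoods = likelihoods or LikelihoodSet.default()
        self.priors = priors or PriorMap()
        self.thresholds = thresholds or ThresholdScheme()

    # ------------------------------------------------------------------ #
    @classmethod
    def from_csv(cls, path, **kwargs) -> "LesionReclassifier":
        """Build the model from a lesion-table CSV (droplet counts allowed)."""
        from .io import load_lesion_table

        return cls(load_lesion_table(path), **kwargs)

    @classmethod
    def from_counts(
        cls, counts: Mapping[tuple, int], **kwargs
    ) -> "LesionReclassifier":
        """Build the model from ``{(category, status): n}`` cell counts.

        Convenient for entering a published cross-tabulation directly.
        """
        rows = []
        i = 0
        for (category, status), n in counts.items():
            if n < 0:
                raise ValueError(f"negative count for cell ({category}, {status})")
            for _ in range(int(n)):
                i += 1
                rows.append(
                    {
                        "lesion_id": f"C{i:03d}",
                        "preliminary_category": Category.parse(category).value,
                        "tertp_status": Call(status).value,
                    }
                )
        return cls(pd.DataFrame(rows), **kwargs)

    # ------------------------------------------------------------------ #
    def fit(self) -> "ReclassificationResults":
        """Run the prior -> posterior -> band pipeline over the cohort."""
        frame = self.data.copy(deep=True)
        uncertain = frame["preliminary_category"].isin(
            [c.value for c in UNCERTAIN_CATEGORIES]
        )
        conclusive = frame["tertp_status"].isin(
            [Call.MUTATED.value, Call.WILDTYPE.value]
        )
        tested = uncertain & conclusive

        # Posterior for each of the 6 (uncertain category x conclusive status)
        # cells; each lesion then takes its cell's value.
        cell_posterior = {
            (cat.value, call.value): posterior_malignant(
                self.priors[cat], self.likelihoods, call
            )
            for cat in UNCERTAIN_CATEGORIES
            for call in (Call.MUTATED, Call.WILDTYPE)
        }
        prior = np.full(len(frame), np.nan)
        posterior = np.full(len(frame), np.nan)
        final = frame["preliminary_category"].to_numpy(dtype=object).copy()
        for pos, (idx, row) in enumerate(frame.iterrows()):
            cat = row["preliminary_category"]
            if cat in (c.value for c in UNCERTAIN_CATEGORIES):
                prior[pos] = self.priors[cat]
                if tested.iloc[pos]:
                    p = cell_posterior[(cat, row["tertp_status"])]
                    posterior[pos] = p
                    final[pos] = classify_posterior(p, self.thresholds).value
                else:
                    posterior[pos] = prior[pos]  # no evidence: posterior = prior
        frame["prior"] = prior
        frame["posterior"] = posterior
        frame["final_category"] = final
        frame["final_group"] = [management_group(c).value for c in final]
        frame["tested"] = tested.to_numpy()
        frame["inconclusive_assay"] = (uncertain & ~conclusive).to_numpy()
        return ReclassificationResults(self, frame)


class ReclassificationResults:
    """Fitted cohort: per-lesion posteriors plus the summary tables."""

    def __init__(self, model: LesionReclassifier, data: pd.DataFrame):
        self.model = model
        self.data = data

    # -- counts ---------------------------------------------------------- #
    @property
    def n_lesions(self) -> int:
        return len(self.data)

    @property
    def n_uncertain(self) -> int:
        return int(
            self.data["preliminary_category"]
            .isin([c.value for c in UNCERTAIN_CATEGORIES])
            .sum()
        )

    @property
    def n_tested(self) -> int:
        """Uncertain lesions with a conclusive TERTp result."""
        return int(self.data["tested"].sum())

    @property
    def n_inconclusive(self) -> int:
        return int(self.data["inconclusive_assay"].sum())

    # -- tables ---------------------------------------------------------- #
    def status_by_category(self, include_inconclusive: bool = False) -> pd.DataFrame:
        """TERTp status x preliminary category cross-tab of the uncertain cohort."""
        sub = self.data[
            self.data["preliminary_category"].isin(
                [c.value for c in UNCERTAIN_CATEGORIES]
            )
        ]
        if not include_inconclusive:
            sub = sub[sub["tested"]]
        tab = pd.crosstab(sub["tertp_status"], sub["preliminary_category"])
        cats = ["likely_benign", "ambiguous", "likely_malignant"]
        statuses = [s for s in _STATUS_ORDER if include_inconclusive or s != "inconclusive"]
        tab = tab.reindex(index=statuses, columns=cats, fill_value=0)
        tab["total"] = tab.sum(axis=1)
        return tab

    @property
    def final_band_counts(self) -> pd.Series:
        """Final diagnostic band counts among conclusively tested lesions."""
        sub = self.data[self.data["tested"]]
        return sub["final_category"].value_counts().reindex(_BAND_ORDER, fill_value=0)

    @property
    def final_groups(self) -> dict:
        """Management-group tallies among conclusively tested lesions."""
        sub = self.data[self.data["tested"]]
        counts = sub["final_group"].value_counts().reindex(_GROUP_ORDER, fill_value=0)
        return {g: int(counts[g]) for g in _GROUP_ORDER}

    def reclassification_table(self) -> pd.DataFrame:
        """Before/after counts per preliminary category (tested lesions only)."""
        sub = self.data[self.data["tested"]]
        tab = pd.crosstab(sub["preliminary_category"], sub["final_category"])
        cats = ["likely_benign", "ambiguous", "likely_malignant"]
        return tab.reindex(index=cats, columns=_BAND_ORDER, fill_value=0)

    @property
    def uncertainty_reduction(self) -> float:
        """Fraction of tested lesions gaining diagnostic certainty.

        Operationalised as lesions finalised in the benign management group
        plus preliminarily ambiguous lesions finalised in the malignant
        group, over all conclusively tested lesions.  (Likely-malignant
        lesions confirmed malignant are not counted: their management was
        already the melanoma pathway.)
        """
        sub = self.data[self.data["tested"]]
        if len(sub) == 0:
            return float("nan")
        benign_final = (sub["final_group"] == ManagementGroup.BENIGN.value).sum()
        amb_to_mal = (
            (sub["preliminary_category"] == Category.AMBIGUOUS.value)
            & (sub["final_group"] == ManagementGroup.MALIGNANT.value)
        ).sum()
        return float(benign_final + amb_to_mal) / len(sub)

    def posterior_grid(self) -> pd.DataFrame:
        """Posterior of malignancy by status (rows) and category prior (columns)."""
        return posterior_grid(self.model.priors, self.model.likelihoods)

    # -- costing --------------------------------------------------------- #
    def cost_comparison(self, config: Optional[CostConfig] = None) -> ScenarioComparison:
        """Two-scenario micro-costing comparison for this fitted cohort."""
        return scenario_costs(self, config)

    # -- calibration (simulated cohorts) --------------------------------- #
    def calibration_table(self) -> pd.DataFrame:
        """Per final band: n, mean posterior, and empirical malignant fraction.

        Requires a ``true_state`` column (simulated cohorts); under the
        generative model the empirical fraction should match the mean
        posterior up to binomial noise.
        """
        if "true_state" not in self.data.columns:
            raise ValueError("calibration requires a true_state column")
        sub = self.data[self.data["tested"]]
        if len(sub) == 0:
            return pd.DataFrame(
                columns=["band", "n", "mean_posterior", "malignant_fraction"]
            ).set_index("band")
        grouped = sub.assign(is_mal=sub["true_state"] == "malignant").groupby(
            "final_category"
        )
        table = grouped.agg(
            n=("posterior", "size"),
            mean_posterior=("posterior", "mean"),
            malignant_fraction=("is_mal", "mean"),
        )
        table.index.name = "band"
        return table.reindex([b for b in _BAND_ORDER if b in table.index])

    # -- presentation ---------------------------------------------------- #
    def summary(self) -> str:
        lk = self.model.likelihoods
        lines = [
            "TERTp Bayesian reclassification",
            "=" * 55,
            f"Lesions: {self.n_lesions} total, {self.n_uncertain} uncertain, "
            f"{self.n_tested} conclusively tested, {self.n_inconclusive} inconclusive assay",
            f"Likelihoods: P(+|mal)={lk.p_pos_given_mal:g}  P(+|ben)={lk.p_pos_given_ben:g}"
            f"  (LR+ = {lk.positive_lr:.1f})",
            "",
            "Posterior grid P(malignant | status, prior):",
            self.posterior_grid().round(2).to_string(),
            "",
            "TERTp status by preliminary category (conclusive results):",
            self.status_by_category().to_string(),
            "",
            "Final bands (tested lesions): "
            + ", ".join(f"{k}={v}" for k, v in self.final_band_counts.items() if v),
            "Management groups: "
            + ", ".join(f"{k}={v}" for k, v in self.final_groups.items()),
        ]
        if self.n_tested:
            lines.append(
                f"Uncertainty reduction: {self.uncertainty_reduction:.0%} "
                f"of {self.n_tested} tested lesions"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<ReclassificationResults: {self.n_lesions} lesions, "
            f"{self.n_tested} tested>"
        )
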