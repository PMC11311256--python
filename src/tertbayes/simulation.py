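"""Synthetic cohorts and Monte Carlo microsimulation of the testing pathway.

The generator draws lesion cohorts with the statistical structure of the
reference case series and propagates them through calling, Bayesian
reclassification and micro-costing:

1. each lesion's preliminary category is drawn from the category mix
   (default proportional to the 115/49/87/39/77 split of the 367-case
   series);
2. its latent true state is Bernoulli with the category's malignancy rate —
   by default the same 0.25/0.5/0.75 priors the inference uses for the
   uncertain categories (the well-specified case needed for calibration
   testing), 0 for confidently benign and 1 for confidently malignant
   lesions, which bypass testing;
3. uncertain lesions receive an assay outcome: inconclusive with the
   assay-failure probability (default 24/175), otherwise mutated with
   probability P(+|malignant) or P(+|benign) according to the true state.

A ``true_malignancy_rates`` override supports misspecified-truth
robustness experiments.  All draws derive from one seed through
``numpy.random.SeedSequence`` substreams, so cohorts and replicate sets are
exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .bayes import Category, PriorMap, ThresholdScheme
from .calling import Call
from .costing import CostConfig
from .evidence import LikelihoodSet
from .model import LesionReclassifier

__all__ = ["SimParams", "SavingsDistribution", "simulate_cohort", "microsimulate"]

#: Category mix of the reference series: 115 benign, 49 likely benign,
#: 87 ambiguous, 39 likely malignant, 77 malignant of 367 lesions.
DEFAULT_CATEGORY_COUNTS = {
    Category.BENIGN: 115,
    Category.LIKELY_BENIGN: 49,
    Category.AMBIGUOUS: 87,
    Category.LIKELY_MALIGNANT: 39,
    Category.MALIGNANT: 77,
}

#: Assay-failure rate among uncertain lesions (24 of 175).
DEFAULT_ASSAY_FAILURE_RATE = 24 / 175


def _default_mix() -> dict:
    total = sum(DEFAULT_CATEGORY_COUNTS.values())
    return {cat: n / total for cat, n in DEFAULT_CATEGORY_COUNTS.items()}


@dataclass(frozen=True)
class SimParams:
    """Generative parameters of a synthetic cohort."""

    n_lesions: int = 367
    category_mix: Mapping[Category, float] = field(default_factory=_default_mix)
    priors: PriorMap = field(default_factory=PriorMap)
    likelihoods: LikelihoodSet = field(default_factory=LikelihoodSet.default)
    assay_failure_rate: float = DEFAULT_ASSAY_FAILURE_RATE
    benign_true_rate: float = 0.0
    malignant_true_rate: float = 1.0
    true_malignancy_rates: Optional[Mapping[Category, float]] = None
    seed: int = 0

    def __post_init__(self):
        if self.n_lesions < 1:
            raise ValueError("n_lesions must be >= 1")
        mix = {Category.parse(k): float(v) for k, v in self.category_mix.items()}
        if any(p < 0 for p in mix.values()) or abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("category_mix must be non-negative and sum to 1")
        object.__setattr__(self, "category_mix", mix)
        for name in ("assay_failure_rate", "benign_true_rate", "malignant_true_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.true_malignancy_rates is not None:
            rates = {
                Category.parse(k): float(v)
                for k, v in self.true_malignancy_rates.items()
            }
            if any(not 0.0 <= p <= 1.0 for p in rates.values()):
                raise ValueError("true_malignancy_rates must lie in [0, 1]")
            object.__setattr__(self, "true_malignancy_rates", rates)

    def true_rate(self, category: Category) -> float:
        """Latent malignancy probability for one category."""
        if self.true_malignancy_rates and category in self.true_malignancy_rates:
            return self.true_malignancy_rates[category]
        if category is Category.BENIGN:
            return self.benign_true_rate
        if category is Category.MALIGNANT:
            return self.malignant_true_rate
        return self.priors[category]


def simulate_cohort(
    params: SimParams, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Draw one synthetic lesion cohort.

    Returns a lesion table with columns ``lesion_id``,
    ``preliminary_category``, ``tertp_status`` (empty for untested
    benign/malignant lesions) and the latent ``true_state``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    n = params.n_lesions
    cats = list(params.category_mix.keys())
    probs = np.array([params.category_mix[c] for c in cats])
    cat_idx = rng.choice(len(cats), size=n, p=probs)
    categories = np.array([cats[i].value for i in cat_idx], dtype=object)

    rates = np.array([params.true_rate(cats[i]) for i in cat_idx])
    malignant = rng.random(n) < rates

    uncertain = np.isin(
        categories, [c.value for c in (Category.LIKELY_BENIGN, Category.AMBIGUOUS, Category.LIKELY_MALIGNANT)]
    )
    status = np.full(n, None, dtype=object)
    failed = rng.random(n) < params.assay_failure_rate
    p_pos = np.where(
        malignant, params.likelihoods.p_pos_given_mal, params.likelihoods.p_pos_given_ben
    )
    mutated = rng.random(n) < p_pos
    status[uncertain & failed] = Call.INCONCLUSIVE.value
    status[uncertain & ~failed & mutated] = Call.MUTATED.value
    status[uncertain & ~failed & ~mutated] = Call.WILDTYPE.value

    return pd.DataFrame(
        {
            "lesion_id": [f"S{i + 1:05d}" for i in range(n)],
            "preliminary_category": categories,
            "tertp_status": status,
            "true_state": np.where(malignant, "malignant", "benign"),
        }
    )


@dataclass(frozen=True)
class SavingsDistribution:
    """Replicate-level cost savings (scenario A minus scenario B), in euros."""

    savings: np.ndarray
    n_lesions: int

    @property
    def n_reps(self) -> int:
        return len(self.savings)

    @property
    def mean(self) -> float:
        return float(np.mean(self.savings))

    @property
    def interval(self) -> tuple:
        """Central 95% interval (2.5th and 97.5th percentiles)."""
        lo, hi = np.percentile(self.savings, [2.5, 97.5])
        return float(lo), float(hi)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"replicate": np.arange(1, self.n_reps + 1), "savings": self.savings}
        )

    def summary(self) -> str:
        lo, hi = self.interval
        return (
            f"Microsimulation: {self.n_reps} cohorts of {self.n_lesions} lesions\n"
            f"mean savings {self.mean:,.2f} EUR  "
            f"(95% interval {lo:,.2f} to {hi:,.2f} EUR)\n"
            f"P(savings > 0) = {float(np.mean(self.savings > 0)):.3f}"
        )


def microsimulate(
    params: SimParams,
    n_reps: int = 500,
    cost_config: Optional[CostConfig] = None,
    thresholds: Optional[ThresholdScheme] = None,
) -> SavingsDistribution:
    """Monte Carlo distribution of scenario savings over replicate cohorts.

    Each replicate draws a fresh cohort, fits the reclassification model
    with the same likelihoods/priors the generator used, and computes the
    two-scenario cost comparison.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    cost_config = cost_config or CostConfig()
    streams = np.random.SeedSequence(params.seed).spawn(n_reps)
    out = np.empty(n_reps)
    for i, ss in enumerate(streams):
        cohort = simulate_cohort(params, rng=np.random.default_rng(ss))
        results = LesionReclassifier(
            cohort,
            likelihoods=params.likelihoods,
            priors=params.priors,
            thresholds=thresholds,
        ).fit()
        out[i] = float(results.cost_comparison(cost_config).savings)
    return SavingsDistribution(savings=out, n_lesions=params.n_lesions)
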