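"""Bayesian update of the histopathological prior with TERTp mutation status.

A lesion with an uncertain preliminary histopathological diagnosis carries a
prior probability of malignancy pi determined by its category (likely benign
0.25, ambiguous 0.5, likely malignant 0.75).  Observing the TERTp test
result updates it by Bayes' rule:

    P(malignant | +) = s * pi / (s * pi + f * (1 - pi))
    P(malignant | -) = (1-s) * pi / ((1-s) * pi + (1-f) * (1 - pi))

with s = P(+|malignant) and f = P(+|benign) from a
:class:`~tertbayes.evidence.LikelihoodSet`.  The posterior is then mapped to
a final diagnostic band:

    [0, 0.1) benign | [0.1, 0.2) likely benign | [0.2, 0.5] ambiguous |
    (0.5, 0.9] likely malignant | (0.9, 1] malignant

The half-open conventions at 0.1/0.2/0.5/0.9 are fixed so that the bands
partition [0, 1] and reproduce every published example classification
(0.17 -> likely benign, 0.37 -> ambiguous, 0.64 -> likely malignant,
0.91/0.97/0.99 -> malignant).  An inconclusive assay short-circuits: the
lesion keeps its preliminary category and is flagged, excluded from
tested-cohort denominators downstream.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Union

from .calling import Call, TertpStatus
from .evidence import LikelihoodSet

__all__ = [
    "Category",
    "UNCERTAIN_CATEGORIES",
    "ManagementGroup",
    "PriorMap",
    "ThresholdScheme",
    "PosteriorResult",
    "posterior_malignant",
    "classify_posterior",
    "reclassify_lesion",
    "management_group",
    "posterior_grid",
]


class Category(str, enum.Enum):
    """Diagnostic category: preliminary (histopathology) or final (band label)."""

    BENIGN = "benign"
    LIKELY_BENIGN = "likely_benign"
    AMBIGUOUS = "ambiguous"
    LIKELY_MALIGNANT = "likely_malignant"
    MALIGNANT = "malignant"

    @classmethod
    def parse(cls, label: str) -> "Category":
        if isinstance(label, cls):
            return label
        norm = str(label).strip().lower().replace(" ", "_").replace("-", "_")
        try:
            return cls(norm)
        except ValueError:
            raise ValueError(f"unknown diagnostic category {label!r}") from None


#: Categories eligible for TERTp testing: confident benign/malignant diagnoses
#: bypass the molecular work-up entirely.
UNCERTAIN_CATEGORIES = frozenset(
    {Category.LIKELY_BENIGN, Category.AMBIGUOUS, Category.LIKELY_MALIGNANT}
)


class ManagementGroup(str, enum.Enum):
    """Three-way management grouping of the five diagnostic bands."""

    BENIGN = "benign"
    UNCERTAIN = "uncertain"
    MALIGNANT = "malignant"


def management_group(category: Category) -> ManagementGroup:
    """Map a band/category to its management group.

    benign + likely_benign -> no further action; ambiguous -> 5 mm margin
    re-excision; likely_malignant + malignant -> melanoma pathway.
    """
    category = Category.parse(category)
    if category in (Category.BENIGN, Category.LIKELY_BENIGN):
        return ManagementGroup.BENIGN
    if category is Category.AMBIGUOUS:
        return ManagementGroup.UNCERTAIN
    return ManagementGroup.MALIGNANT


@dataclass(frozen=True)
class PriorMap:
    """Prior probability of malignancy per uncertain preliminary category."""

    priors: Mapping[Category, float] = field(
        default_factory=lambda: {
            Category.LIKELY_BENIGN: 0.25,
            Category.AMBIGUOUS: 0.5,
            Category.LIKELY_MALIGNANT: 0.75,
        }
    )

    def __post_init__(self):
        norm = {Category.parse(k): float(v) for k, v in self.priors.items()}
        for cat, p in norm.items():
            if cat not in UNCERTAIN_CATEGORIES:
                raise ValueError(f"priors only apply to uncertain categories, got {cat}")
            if not 0.0 < p < 1.0:
                raise ValueError(f"prior for {cat.value} must lie strictly in (0, 1), got {p}")
        if set(norm) != UNCERTAIN_CATEGORIES:
            missing = {c.value for c in UNCERTAIN_CATEGORIES - set(norm)}
            raise ValueError(f"missing priors for {sorted(missing)}")
        object.__setattr__(self, "priors", norm)

    def __getitem__(self, category) -> float:
        return self.priors[Category.parse(category)]


@dataclass(frozen=True)
class ThresholdScheme:
    """Cut-points of the five posterior bands on [0, 1]."""

    benign_lt: float = 0.1
    likely_benign_lt: float = 0.2
    ambiguous_hi: float = 0.5
    malignant_gt: float = 0.9

    def __post_init__(self):
        if not (
            0.0
            < self.benign_lt
            < self.likely_benign_lt
            <= self.ambiguous_hi
            < self.malignant_gt
            < 1.0
        ):
            raise ValueError(
                "thresholds must satisfy 0 < benign_lt < likely_benign_lt "
                "<= ambiguous_hi < malignant_gt < 1, got "
                f"({self.benign_lt}, {self.likely_benign_lt}, "
                f"{self.ambiguous_hi}, {self.malignant_gt})"
            )


@dataclass(frozen=True)
class PosteriorResult:
    """Outcome of reclassifying one lesion."""

    preliminary: Category
    prior: float
    tertp_status: Call
    posterior: float
    final_category: Category
    inconclusive: bool = False

    @property
    def final_group(self) -> ManagementGroup:
        return management_group(self.final_category)


def _status_label(status: Union[TertpStatus, Call, str]) -> Call:
    if isinstance(status, TertpStatus):
        return status.status
    if isinstance(status, Call):
        return status
    return Call(str(status).strip().lower())


def posterior_malignant(
    prior: float, lk: LikelihoodSet, status: Union[TertpStatus, Call, str]
) -> float:
    """Posterior probability of malignancy given the TERTp result.

    ``status`` must be ``mutated`` or ``wildtype``; an inconclusive result
    carries no evidence and is handled upstream by
    :func:`reclassify_lesion`.
    """
    if not 0.0 <= prior <= 1.0:
        raise ValueError(f"prior must lie in [0, 1], got {prior!r}")
    call = _status_label(status)
    if call is Call.MUTATED:
        p_mal, p_ben = lk.p_pos_given_mal, lk.p_pos_given_ben
    elif call is Call.WILDTYPE:
        p_mal, p_ben = lk.p_neg_given_mal, lk.p_neg_given_ben
    else:
        raise ValueError("posterior undefined for an inconclusive result")
    numerator = p_mal * prior
    denominator = numerator + p_ben * (1.0 - prior)
    if denominator == 0.0:
        raise ZeroDivisionError(
            f"degenerate update: P({call.value}) = 0 under prior {prior} "
            f"with likelihoods P({call.value}|mal)={p_mal}, P({call.value}|ben)={p_ben}"
        )
    return numerator / denominator


def classify_posterior(p: float, scheme: ThresholdScheme | None = None) -> Category:
    """Map a posterior probability to its diagnostic band."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"posterior must lie in [0, 1], got {p!r}")
    scheme = scheme or ThresholdScheme()
    if p < scheme.benign_lt:
        return Category.BENIGN
    if p < scheme.likely_benign_lt:
        return Category.LIKELY_BENIGN
    if p <= scheme.ambiguous_hi:
        return Category.AMBIGUOUS
    if p <= scheme.malignant_gt:
        return Category.LIKELY_MALIGNANT
    return Category.MALIGNANT


def reclassify_lesion(
    preliminary: Category,
    status: Union[TertpStatus, Call, str],
    priors: PriorMap | None = None,
    lk: LikelihoodSet | None = None,
    scheme: ThresholdScheme | None = None,
) -> PosteriorResult:
    """Prior lookup -> Bayesian update -> band classification for one lesion.

    Only uncertain preliminary categories are accepted; confidently benign
    or malignant lesions are not tested.  An inconclusive status leaves the
    lesion in its preliminary category with ``posterior == prior`` and the
    ``inconclusive`` flag set.
    """
    preliminary = Category.parse(preliminary)
    if preliminary not in UNCERTAIN_CATEGORIES:
        raise ValueError(
            f"lesions preliminarily classified {preliminary.value} are not tested; "
            "only likely_benign, ambiguous and likely_malignant enter the work-up"
        )
    priors = priors or PriorMap()
    lk = lk or LikelihoodSet.default()
    scheme = scheme or ThresholdScheme()
    prior = priors[preliminary]
    call = _status_label(status)
    if call is Call.INCONCLUSIVE:
        return PosteriorResult(
            preliminary=preliminary,
            prior=prior,
            tertp_status=call,
            posterior=prior,
            final_category=preliminary,
            inconclusive=True,
        )
    post = posterior_malignant(prior, lk, call)
    return PosteriorResult(
        preliminary=preliminary,
        prior=prior,
        tertp_status=call,
        posterior=post,
        final_category=classify_posterior(post, scheme),
        inconclusive=False,
    )


def posterior_grid(
    priors: PriorMap | None = None, lk: LikelihoodSet | None = None
) -> "pd.DataFrame":
    """The 2 x 3 table of posteriors: TERTp status (rows) by prior (columns)."""
    import pandas as pd

    priors = priors or PriorMap()
    lk = lk or LikelihoodSet.default()
    ordered = sorted(priors.priors.values())
    rows = {}
    for call in (Call.MUTATED, Call.WILDTYPE):
        rows[call.value] = [posterior_malignant(pi, lk, call) for pi in ordered]
    frame = pd.DataFrame(rows, index=ordered).T
    frame.index.name = "tertp_status"
    frame.columns.name = "prior"
    return frame
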