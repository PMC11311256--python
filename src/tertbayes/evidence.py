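"""Pooling of published TERT-promoter mutation prevalences into test likelihoods.

The probability that a melanoma carries a TERT-promoter (TERTp) hotspot
mutation, P(TERTp+ | malignant), is estimated as a case-weighted average of
published study prevalences.  The benign-side likelihood
P(TERTp+ | benign) is taken as a fixed literature estimate (0.014: the
fraction of melanocytic nevi found to carry a TERTp mutation in the largest
published nevus series).  Together the four conditional probabilities form a
:class:`LikelihoodSet`, the evidence term of the Bayesian update in
:mod:`tertbayes.bayes`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "StudyRecord",
    "LikelihoodSet",
    "weighted_prevalence",
    "build_likelihood_set",
    "read_study_table",
    "write_study_table",
    "DEFAULT_P_POS_GIVEN_BENIGN",
]

#: Fraction of benign melanocytic nevi carrying a TERTp hotspot mutation
#: (largest published nevus series; used as P(TERTp+ | benign)).
DEFAULT_P_POS_GIVEN_BENIGN = 0.014

_SUM_TOL = 1e-12


def _as_fraction(value) -> float:
    """Normalise a prevalence given as ``0.43``, ``'0.43'`` or ``'43%'`` to a fraction."""
    if isinstance(value, str):
        text = value.strip()
        if text.endswith("%"):
            return float(text[:-1].strip()) / 100.0
        return float(text)
    return float(value)


@dataclass(frozen=True)
class StudyRecord:
    """One published study: number of melanomas and their TERTp+ prevalence."""

    study_id: str
    n_cases: int
    prevalence_pos: float

    def __post_init__(self):
        if int(self.n_cases) != self.n_cases or self.n_cases < 1:
            raise ValueError(
                f"study {self.study_id!r}: n_cases must be a positive integer, "
                f"got {self.n_cases!r}"
            )
        object.__setattr__(self, "prevalence_pos", _as_fraction(self.prevalence_pos))
        if not 0.0 <= self.prevalence_pos <= 1.0:
            raise ValueError(
                f"study {self.study_id!r}: prevalence_pos must lie in [0, 1], "
                f"got {self.prevalence_pos!r}"
            )


@dataclass(frozen=True)
class LikelihoodSet:
    """The four conditional probabilities P(test result | disease state).

    ``p_pos_given_mal``/``p_neg_given_mal`` are the mutated / wild-type
    probabilities in melanoma; ``p_pos_given_ben``/``p_neg_given_ben`` the
    same in benign lesions.  Each pair must sum to one.
    """

    p_pos_given_mal: float
    p_neg_given_mal: float
    p_pos_given_ben: float
    p_neg_given_ben: float

    def __post_init__(self):
        for name, p in vars(self).items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p!r}")
        if abs(self.p_pos_given_mal + self.p_neg_given_mal - 1.0) > _SUM_TOL:
            raise ValueError("p_pos_given_mal + p_neg_given_mal must equal 1")
        if abs(self.p_pos_given_ben + self.p_neg_given_ben - 1.0) > _SUM_TOL:
            raise ValueError("p_pos_given_ben + p_neg_given_ben must equal 1")

    @property
    def positive_lr(self) -> float:
        """Likelihood ratio of a mutated result, P(+|mal) / P(+|ben)."""
        if self.p_pos_given_ben == 0.0:
            raise ZeroDivisionError("positive likelihood ratio undefined: P(+|benign) = 0")
        return self.p_pos_given_mal / self.p_pos_given_ben

    @classmethod
    def default(cls, rounded: bool = True) -> "LikelihoodSet":
        """The package's reference likelihoods.

        ``rounded=True`` (default) gives {0.41, 0.59, 0.014, 0.986}, the
        two-decimal estimate printed alongside the pooled prevalence;
        ``rounded=False`` keeps the unrounded pooled value 0.4122.
        """
        prev = weighted_prevalence(reference_studies())
        return build_likelihood_set(
            prev, DEFAULT_P_POS_GIVEN_BENIGN, rounding_decimals=2 if rounded else None
        )


def weighted_prevalence(studies: Sequence[StudyRecord] | Iterable[StudyRecord]) -> float:
    """Case-weighted average prevalence, sum(n_i * p_i) / sum(n_i).

    Raises ``ValueError`` on an empty study list; individual records
    validate themselves on construction.
    """
    studies = list(studies)
    if not studies:
        raise ValueError("cannot pool an empty list of studies")
    total = sum(s.n_cases for s in studies)
    return sum(s.n_cases * s.prevalence_pos for s in studies) / total


def build_likelihood_set(
    prev_pos_mal: float,
    prev_pos_ben: float,
    rounding_decimals: int | None = None,
) -> LikelihoodSet:
    """Build a :class:`LikelihoodSet` from the two positive-result prevalences.

    When ``rounding_decimals`` is given, ``p_pos_given_mal`` is rounded first
    and its complement derived from the rounded value, so that the pair still
    sums to one exactly (0.4122 -> 0.41 / 0.59 at two decimals).
    """
    for name, p in (("prev_pos_mal", prev_pos_mal), ("prev_pos_ben", prev_pos_ben)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {p!r}")
    if rounding_decimals is not None:
        prev_pos_mal = round(prev_pos_mal, rounding_decimals)
    return LikelihoodSet(
        p_pos_given_mal=prev_pos_mal,
        p_neg_given_mal=1.0 - prev_pos_mal,
        p_pos_given_ben=prev_pos_ben,
        p_neg_given_ben=1.0 - prev_pos_ben,
    )


def read_study_table(path) -> list[StudyRecord]:
    """Read a study table CSV with header ``study_id,n_cases,prevalence_pos``.

    Prevalences may be fractions (``0.43``) or percent strings (``43%``).
    """
    frame = pd.read_csv(path, dtype={"study_id": str})
    missing = {"study_id", "n_cases", "prevalence_pos"} - set(frame.columns)
    if missing:
        raise ValueError(f"study table {path}: missing columns {sorted(missing)}")
    return [
        StudyRecord(row.study_id, int(row.n_cases), _as_fraction(row.prevalence_pos))
        for row in frame.itertuples(index=False)
    ]


def write_study_table(studies: Sequence[StudyRecord], path) -> None:
    pd.DataFrame(
        {
            "study_id": [s.study_id for s in studies],
            "n_cases": [s.n_cases for s in studies],
            "prevalence_pos": [s.prevalence_pos for s in studies],
        }
    ).to_csv(path, index=False)


def reference_studies() -> list[StudyRecord]:
    """The packaged reference study table (ten melanoma prevalence studies)."""
    from . import datasets

    return datasets.reference_studies()
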