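"""Packaged reference tables.

``reference_studies`` is the ten-study melanoma prevalence table used to
pool P(TERTp+ | malignant).  ``uncertain_cohort`` reconstructs the
175-lesion uncertain cohort of the reference case series from its printed
marginal counts: 49 likely benign (44 wild-type, 5 inconclusive),
87 ambiguous (55 wild-type, 14 mutated — 6 C228T / 8 C250T, 18
inconclusive) and 39 likely malignant (13 wild-type, 25 mutated — 7 C228T /
18 C250T, 1 inconclusive).  No lesion-level data were ever deposited, so
the droplet counts attached to each row are synthetic: deterministic values
chosen to be consistent with each lesion's published status under the
ddPCR calling rule (>=6 mutant droplets mutated; <6 mutant with >=600
total positive wild-type).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .calling import Call
from .evidence import StudyRecord

__all__ = [
    "reference_studies",
    "reference_study_path",
    "uncertain_cohort",
    "build_uncertain_cohort",
]

#: (study_id, n_cases, prevalence of TERTp+ melanomas) for the ten pooled studies.
_REFERENCE_STUDIES = [
    ("Griewank 2013", 38, 0.31),
    ("Griewank 2014", 362, 0.43),
    ("Populo 2014", 116, 0.22),
    ("Egberts 2016", 96, 0.49),
    ("Nagore 2016", 300, 0.42),
    ("Ofner 2017", 40, 0.55),
    ("Roh 2017", 88, 0.17),
    ("Zehir 2017", 164, 0.75),
    ("de Unamuno Bustos 2018", 170, 0.31),
    ("Tan 2019", 133, 0.32),
]

# (preliminary category, status, detected variant or None, count)
_COHORT_MARGINALS = [
    ("likely_benign", Call.WILDTYPE, None, 44),
    ("likely_benign", Call.INCONCLUSIVE, None, 5),
    ("ambiguous", Call.WILDTYPE, None, 55),
    ("ambiguous", Call.MUTATED, "C228T", 6),
    ("ambiguous", Call.MUTATED, "C250T", 8),
    ("ambiguous", Call.INCONCLUSIVE, None, 18),
    ("likely_malignant", Call.WILDTYPE, None, 13),
    ("likely_malignant", Call.MUTATED, "C228T", 7),
    ("likely_malignant", Call.MUTATED, "C250T", 18),
    ("likely_malignant", Call.INCONCLUSIVE, None, 1),
]


def reference_study_path():
    """Path-like handle to the packaged study-table CSV."""
    return resources.files("tertbayes.data") / "reference_studies.csv"


def reference_studies() -> list[StudyRecord]:
    return [StudyRecord(*row) for row in _REFERENCE_STUDIES]


def _droplets_for(status: Call, variant: str | None, i: int):
    """Synthetic but rule-consistent droplet counts for one lesion."""
    wt = (0, 700 + 10 * (i % 25))  # clean negative on a well-loaded assay
    fail = (0, 50 + 5 * (i % 20))  # too few droplets to call negative
    if status is Call.MUTATED:
        mut = (10 + i % 40, 800 + 10 * (i % 25))
        c228, c250 = (mut, wt) if variant == "C228T" else (wt, mut)
    elif status is Call.WILDTYPE:
        c228, c250 = wt, wt
    else:
        c228, c250 = fail, fail
    return c228, c250


def build_uncertain_cohort(droplet_counts: bool = True) -> pd.DataFrame:
    """Reconstruct the uncertain cohort lesion table from its marginal counts."""
    rows = []
    i = 0
    for category, status, variant, n in _COHORT_MARGINALS:
        for _ in range(n):
            i += 1
            row = {
                "lesion_id": f"L{i:03d}",
                "preliminary_category": category,
                "tertp_status": status.value,
            }
            if droplet_counts:
                (m228, t228), (m250, t250) = _droplets_for(status, variant, i)
                row.update(
                    mutant_droplets_c228t=m228,
                    total_droplets_c228t=t228,
                    mutant_droplets_c250t=m250,
                    total_droplets_c250t=t250,
                )
            rows.append(row)
    columns = [
        "lesion_id",
        "preliminary_category",
        "mutant_droplets_c228t",
        "total_droplets_c228t",
        "mutant_droplets_c250t",
        "total_droplets_c250t",
        "tertp_status",
    ]
    frame = pd.DataFrame(rows)
    if not droplet_counts:
        columns = ["lesion_id", "preliminary_category", "tertp_status"]
    return frame[columns]


def uncertain_cohort() -> pd.DataFrame:
    """The packaged uncertain-cohort lesion table (175 rows)."""
    path = resources.files("tertbayes.data") / "uncertain_cohort.csv"
    with resources.as_file(path) as p:
        return pd.read_csv(p)
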