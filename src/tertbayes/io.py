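"""Readers, writers, configuration, and the end-to-end pipeline.

All tables are plain CSV (comma separator, UTF-8, dot decimal point).  The
lesion table schema is::

    lesion_id,preliminary_category,mutant_droplets_c228t,total_droplets_c228t,
    mutant_droplets_c250t,total_droplets_c250t,tertp_status

Droplet columns are optional; when present and a ``tertp_status`` is also
given, the recorded status must agree with the status called from the
droplet counts, otherwise loading fails with a row-addressed error.  When
the status is absent it is derived from the counts.  Category labels are
case-insensitive on input and canonical snake_case on output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .bayes import Category, PriorMap, ThresholdScheme
from .calling import Assay, Call, DropletCounts, call_assay, combine_assays
from .costing import CostConfig, CostItem, ScenarioComparison
from .evidence import LikelihoodSet, read_study_table, weighted_prevalence
from .model import LesionReclassifier, ReclassificationResults

__all__ = [
    "load_lesion_table",
    "write_lesion_table",
    "load_cost_config",
    "PipelineConfig",
    "ReportBundle",
    "run_pipeline",
]

_DROPLET_COLS = [
    "mutant_droplets_c228t",
    "total_droplets_c228t",
    "mutant_droplets_c250t",
    "total_droplets_c250t",
]


def _row_error(path, index, message) -> ValueError:
    return ValueError(f"{path}, row {index + 2}: {message}")  # +2: header + 1-basing


def load_lesion_table(path) -> pd.DataFrame:
    """Load and validate a lesion table, resolving droplet counts to calls."""
    frame = pd.read_csv(path, dtype={"lesion_id": str})
    if "preliminary_category" not in frame.columns:
        raise ValueError(f"{path}: missing required column preliminary_category")
    has_droplets = all(c in frame.columns for c in _DROPLET_COLS)
    has_status = "tertp_status" in frame.columns
    if not (has_droplets or has_status):
        raise ValueError(
            f"{path}: need either a tertp_status column or the four droplet-count columns"
        )

    categories, statuses = [], []
    for i, row in frame.iterrows():
        try:
            categories.append(Category.parse(row["preliminary_category"]).value)
        except ValueError as exc:
            raise _row_error(path, i, str(exc)) from None

        recorded = None
        if has_status and isinstance(row.get("tertp_status"), str) and row["tertp_status"].strip():
            try:
                recorded = Call(row["tertp_status"].strip().lower())
            except ValueError:
                raise _row_error(
                    path, i, f"unknown tertp_status {row['tertp_status']!r}"
                ) from None

        called = None
        if has_droplets and not any(pd.isna(row[c]) for c in _DROPLET_COLS):
            try:
                c228 = call_assay(
                    DropletCounts(
                        Assay.C228T,
                        int(row["mutant_droplets_c228t"]),
                        int(row["total_droplets_c228t"]),
                    )
                )
                c250 = call_assay(
                    DropletCounts(
                        Assay.C250T,
                        int(row["mutant_droplets_c250t"]),
                        int(row["total_droplets_c250t"]),
                    )
                )
            except (ValueError, TypeError) as exc:
                raise _row_error(path, i, f"malformed droplet counts: {exc}") from None
            called = combine_assays(c228, c250).status

        if recorded is not None and called is not None and recorded is not called:
            raise _row_error(
                path,
                i,
                f"recorded status {recorded.value!r} contradicts droplet counts "
                f"(called {called.value!r})",
            )
        final = recorded or called
        statuses.append(final.value if final is not None else None)

    out = frame.copy()
    out["preliminary_category"] = categories
    out["tertp_status"] = statuses
    return out


def write_lesion_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def load_cost_config(path) -> CostConfig:
    """Read a YAML cost configuration.

    Keys: ``cost_reexcision``, ``cost_tert_test``, optional ``cost_items``
    (list of per-activity component mappings), ``batch_discount_fraction``,
    ``include_inconclusive_as_ambiguous``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    items = None
    if raw.get("cost_items"):
        items = tuple(CostItem(**item) for item in raw["cost_items"])
    kwargs = {
        k: raw[k]
        for k in (
            "cost_reexcision",
            "cost_tert_test",
            "batch_discount_fraction",
            "include_inconclusive_as_ambiguous",
        )
        if k in raw
    }
    return CostConfig(cost_items=items, **kwargs)


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs."""

    lesion_table: Optional[str] = None
    study_table: Optional[str] = None
    cost_config: Optional[str] = None
    rounding_decimals: Optional[int] = 2
    priors: PriorMap = field(default_factory=PriorMap)
    thresholds: ThresholdScheme = field(default_factory=ThresholdScheme)
    output_dir: Optional[str] = None

    def resolve_likelihoods(self) -> tuple[LikelihoodSet, float]:
        from . import datasets
        from .evidence import DEFAULT_P_POS_GIVEN_BENIGN, build_likelihood_set

        studies = (
            read_study_table(self.study_table)
            if self.study_table
            else datasets.reference_studies()
        )
        pooled = weighted_prevalence(studies)
        lk = build_likelihood_set(
            pooled, DEFAULT_P_POS_GIVEN_BENIGN, rounding_decimals=self.rounding_decimals
        )
        return lk, pooled

    def resolve_cost_config(self) -> CostConfig:
        return load_cost_config(self.cost_config) if self.cost_config else CostConfig()


@dataclass
class ReportBundle:
    """Rendered outputs of one pipeline run; every number is recomputed."""

    pooled_prevalence: float
    likelihoods: LikelihoodSet
    results: ReclassificationResults
    comparison: ScenarioComparison
    parameters: dict

    def write(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.results.posterior_grid().round(4).to_csv(outdir / "posterior_grid.csv")
        self.results.status_by_category(include_inconclusive=True).to_csv(
            outdir / "status_by_category.csv"
        )
        self.results.final_band_counts.rename("n").to_csv(outdir / "final_bands.csv")
        self.results.reclassification_table().to_csv(
            outdir / "reclassification_table.csv"
        )
        self.comparison.to_frame().to_csv(outdir / "cost_comparison.csv", index=False)
        self.results.data.to_csv(outdir / "lesions_reclassified.csv", index=False)
        with open(outdir / "run_log.json", "w") as fh:
            json.dump(self.parameters, fh, indent=2, default=str)
        return outdir

    def summary(self) -> str:
        from .costing import format_eur

        comp = self.comparison
        return "\n".join(
            [
                self.results.summary(),
                "",
                f"Pooled P(TERTp+|malignant): {self.pooled_prevalence:.4f}",
                "Cost comparison (tested uncertain lesions only):",
                f"  scenario A (re-excise all): {format_eur(comp.total_a)}",
                f"  scenario B (test, re-excise residual ambiguous): {format_eur(comp.total_b)}"
                f" = {format_eur(comp.test_total_b)} testing + "
                f"{format_eur(comp.reexcision_total_b)} re-excision",
                f"  savings: {format_eur(comp.savings)}"
                f"  (treatment-cost change {format_eur(comp.treatment_cost_delta)})",
            ]
        )


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Evidence pooling -> calling -> reclassification -> costing, one call."""
    from . import datasets

    lk, pooled = config.resolve_likelihoods()
    lesions = (
        load_lesion_table(config.lesion_table)
        if config.lesion_table
        else datasets.uncertain_cohort()
    )
    model = LesionReclassifier(
        lesions, likelihoods=lk, priors=config.priors, thresholds=config.thresholds
    )
    results = model.fit()
    cost_config = config.resolve_cost_config()
    comparison = results.cost_comparison(cost_config)
    parameters = {
        "lesion_table": config.lesion_table or "<packaged uncertain cohort>",
        "study_table": config.study_table or "<packaged reference studies>",
        "pooled_prevalence": pooled,
        "rounding_decimals": config.rounding_decimals,
        "likelihoods": vars(lk),
        "priors": {c.value: p for c, p in config.priors.priors.items()},
        "thresholds": vars(config.thresholds),
        "cost_reexcision": cost_config.cost_reexcision,
        "cost_tert_test": cost_config.cost_tert_test,
        "n_lesions": results.n_lesions,
        "n_tested": results.n_tested,
        "n_inconclusive": results.n_inconclusive,
    }
    bundle = ReportBundle(
        pooled_prevalence=pooled,
        likelihoods=lk,
        results=results,
        comparison=comparison,
        parameters=parameters,
    )
    if config.output_dir:
        bundle.write(config.output_dir)
    return bundle
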