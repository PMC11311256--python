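"""Micro-costing comparison of the two diagnostic pathways.

Scenario A (no molecular testing): every conclusively testable uncertain
lesion receives a 5 mm margin re-excision at the hospital tariff.
Scenario B (TERTp testing): every such lesion is tested at the per-sample
micro-costed test price, and only lesions that remain in the ambiguous band
after the Bayesian update are re-excised.  Costs of the malignant pathway
(re-excision after a malignant diagnosis, staging, follow-up, therapy) are
excluded from both scenarios by construction: they are indicated and
unavoidable once malignancy is established.

All monetary arithmetic uses :class:`decimal.Decimal` so that totals are
exact to the cent; floats never enter a reported amount.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from typing import Optional, Sequence

__all__ = [
    "CostItem",
    "CostConfig",
    "ScenarioComparison",
    "per_sample_test_cost",
    "scenario_costs",
    "breakeven_resolution_fraction",
    "format_eur",
]

#: Hospital tariff for a 5 mm margin re-excision, per patient.
DEFAULT_COST_REEXCISION = Decimal("1274")
#: Micro-costed per-sample price of the two-assay ddPCR TERTp analysis.
DEFAULT_COST_TERT_TEST = Decimal("570.5")
#: Documented batch discount when >2 samples share a ddPCR run.
REFERENCE_BATCH_DISCOUNT = Decimal("0.33")

_CENT = Decimal("0.01")


def _money(value) -> Decimal:
    """Coerce to Decimal via str so 570.5 means exactly 570.50 €."""
    if isinstance(value, Decimal):
        return value
    return Decimal(str(value))


@dataclass(frozen=True)
class CostItem:
    """One activity's itemised cost components (micro-costing line)."""

    activity: str
    personnel_minutes: Decimal = Decimal(0)
    wage_per_minute: Decimal = Decimal(0)
    materials: Decimal = Decimal(0)
    equipment: Decimal = Decimal(0)
    overhead: Decimal = Decimal(0)
    failure_surcharge: Decimal = Decimal(0)

    def __post_init__(self):
        for name in (
            "personnel_minutes",
            "wage_per_minute",
            "materials",
            "equipment",
            "overhead",
            "failure_surcharge",
        ):
            v = _money(getattr(self, name))
            if v < 0:
                raise ValueError(f"cost item {self.activity!r}: {name} must be >= 0")
            object.__setattr__(self, name, v)

    @property
    def total(self) -> Decimal:
        return (
            self.personnel_minutes * self.wage_per_minute
            + self.materials
            + self.equipment
            + self.overhead
            + self.failure_surcharge
        )


@dataclass(frozen=True)
class CostConfig:
    """Tariffs and options of the costing comparison."""

    cost_reexcision: Decimal = DEFAULT_COST_REEXCISION
    cost_tert_test: Decimal = DEFAULT_COST_TERT_TEST
    cost_items: Optional[tuple] = None
    batch_discount_fraction: Decimal = Decimal(0)
    include_inconclusive_as_ambiguous: bool = False

    def __post_init__(self):
        object.__setattr__(self, "cost_reexcision", _money(self.cost_reexcision))
        object.__setattr__(self, "cost_tert_test", _money(self.cost_tert_test))
        object.__setattr__(
            self, "batch_discount_fraction", _money(self.batch_discount_fraction)
        )
        if self.cost_reexcision < 0 or self.cost_tert_test < 0:
            raise ValueError("tariffs must be >= 0")
        if not Decimal(0) <= self.batch_discount_fraction < Decimal(1):
            raise ValueError("batch_discount_fraction must lie in [0, 1)")
        if self.cost_items is not None:
            items = tuple(self.cost_items)
            object.__setattr__(self, "cost_items", items)
            breakdown = sum((it.total for it in items), Decimal(0))
            if abs(breakdown - self.cost_tert_test) > _CENT:
                raise ValueError(
                    f"cost-item breakdown totals {breakdown} € but cost_tert_test "
                    f"is {self.cost_tert_test} € (must agree within 0.01 €)"
                )


def per_sample_test_cost(
    items: Sequence[CostItem],
    batch_size: int = 1,
    discount: Decimal | float = REFERENCE_BATCH_DISCOUNT,
) -> Decimal:
    """Sum of itemised activity costs, discounted when >2 samples share a run."""
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    discount = _money(discount)
    if not Decimal(0) <= discount < Decimal(1):
        raise ValueError("discount must lie in [0, 1)")
    total = sum((item.total for item in items), Decimal(0))
    if batch_size > 2:
        total *= Decimal(1) - discount
    return total


@dataclass(frozen=True)
class ScenarioComparison:
    """Totals of the two pathways and their differences.

    Group counts refer to the three-way management grouping inside the
    conclusively tested uncertain cohort; confidently benign/malignant
    lesions never enter either scenario's costs.
    """

    n_tested: int
    n_final_ambiguous: int
    groups_a: dict
    groups_b: dict
    reexcision_total_a: Decimal
    test_total_b: Decimal
    reexcision_total_b: Decimal

    @property
    def total_a(self) -> Decimal:
        return self.reexcision_total_a

    @property
    def total_b(self) -> Decimal:
        return self.test_total_b + self.reexcision_total_b

    @property
    def savings(self) -> Decimal:
        """total_A - total_B; positive when testing is the cheaper pathway."""
        return self.total_a - self.total_b

    @property
    def treatment_cost_delta(self) -> Decimal:
        """Change in re-excision spending, B minus A (negative = reduced)."""
        return self.reexcision_total_b - self.reexcision_total_a

    def to_frame(self) -> "pd.DataFrame":
        import pandas as pd

        rows = [
            ("n tested (uncertain, conclusive)", self.n_tested, self.n_tested),
            ("benign group", self.groups_a.get("benign", 0), self.groups_b.get("benign", 0)),
            (
                "uncertain group (re-excised)",
                self.groups_a.get("uncertain", 0),
                self.groups_b.get("uncertain", 0),
            ),
            (
                "malignant group",
                self.groups_a.get("malignant", 0),
                self.groups_b.get("malignant", 0),
            ),
            ("re-excision total (EUR)", self.reexcision_total_a, self.reexcision_total_b),
            ("test total (EUR)", Decimal(0), self.test_total_b),
            ("scenario total (EUR)", self.total_a, self.total_b),
        ]
        frame = pd.DataFrame(rows, columns=["quantity", "scenario_A", "scenario_B"])
        return frame


def scenario_costs(crosstab, config: CostConfig | None = None) -> ScenarioComparison:
    """Compare total pathway costs of the two scenarios.

    ``crosstab`` is any object exposing ``n_tested``, ``n_inconclusive``,
    and ``final_groups`` (mapping management group -> count) — the cohort
    summary produced by :class:`tertbayes.model.ReclassificationResults` —
    or a plain ``(n_tested, n_final_ambiguous)`` tuple.
    """
    config = config or CostConfig()
    if isinstance(crosstab, tuple):
        n_tested, n_ambiguous = crosstab
        groups_b = {"uncertain": n_ambiguous}
        n_inconclusive = 0
    else:
        n_tested = crosstab.n_tested
        n_inconclusive = getattr(crosstab, "n_inconclusive", 0)
        groups_b = {
            str(getattr(k, "value", k)): int(v) for k, v in crosstab.final_groups.items()
        }
        n_ambiguous = groups_b.get("uncertain", 0)
    if n_tested < 0 or n_ambiguous < 0:
        raise ValueError("counts must be non-negative")
    if n_ambiguous > n_tested:
        raise ValueError("final ambiguous count cannot exceed the tested count")
    if config.include_inconclusive_as_ambiguous:
        # Sensitivity analysis: untestable lesions stay ambiguous in both arms.
        n_tested += n_inconclusive
        n_ambiguous += n_inconclusive
        groups_b = dict(groups_b)
        groups_b["uncertain"] = n_ambiguous
    groups_a = {"benign": 0, "uncertain": n_tested, "malignant": 0}
    return ScenarioComparison(
        n_tested=n_tested,
        n_final_ambiguous=n_ambiguous,
        groups_a=groups_a,
        groups_b=groups_b,
        reexcision_total_a=n_tested * config.cost_reexcision,
        test_total_b=n_tested * config.cost_tert_test,
        reexcision_total_b=n_ambiguous * config.cost_reexcision,
    )


def breakeven_resolution_fraction(config: CostConfig | None = None) -> float:
    """Fraction of tested lesions that must leave the ambiguous band to break even.

    Savings per tested lesion are ``cost_reexcision - cost_tert_test -
    P(stay ambiguous) * cost_reexcision``; setting savings to zero gives the
    resolved fraction ``cost_tert_test / cost_reexcision``.
    """
    config = config or CostConfig()
    if config.cost_reexcision == 0:
        raise ZeroDivisionError("break-even undefined: re-excision tariff is zero")
    return float(config.cost_tert_test / config.cost_reexcision)


def format_eur(amount: Decimal, paper_style: bool = False) -> str:
    """Format a euro amount; ``paper_style`` uses European dot-thousands notation."""
    quantised = _money(amount).quantize(_CENT)
    if not paper_style:
        return f"{quantised} €"
    sign = "-" if quantised < 0 else ""
    units, cents = divmod(abs(quantised), 1)
    grouped = f"{int(units):,}".replace(",", ".")
    return f"{sign}{grouped},{int(cents * 100):02d} €"
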