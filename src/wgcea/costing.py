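"""Standardized trial costing: ledgers, allocation rules, currency conversion, summaries.

A trial's resource use arrives as a *cost ledger*: one line item per expense, tagged
with a month index, a category (staff / materials / other recurrent / capital), a
phase (start-up vs implementation) and a flag marking costs shared with
non-intervention activities (research, M&E, other interventions). The functions here
turn such a ledger into the standardized cost summary used throughout the analysis:

* total cost = start-up + implementation over the cost-effectiveness horizon,
* annual figures = amount x 12 / horizon months,
* unit costs per live birth, per person-year and per group-year, using
  factorial-halved denominators for trials that tested a second intervention
  alongside the women's groups,
* category composition shares.

Ledger amounts are held as :class:`decimal.Decimal` so that sums are exact to money
precision; summaries are plain floats. All monetary outputs are 2016 international
dollars once :func:`convert_currency` has been applied.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from decimal import Decimal
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .fixtures import TrialProfile, TrialReportedResults

CATEGORIES = ("staff", "materials", "other_recurrent", "capital")
PHASES = ("startup", "implementation")


@dataclass(frozen=True)
class CostLineItem:
    period: int  # month index from project start, 0-based
    amount: Decimal  # money, source currency until converted
    category: str
    phase: str
    joint: bool = False  # shared with research / M&E / other interventions
    cost_centre: str = ""

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError("amount must be non-negative")
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}, got {self.category!r}")
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")


@dataclass(frozen=True)
class CostLedger:
    """Immutable collection of line items with exact-decimal arithmetic."""

    items: tuple[CostLineItem, ...]

    def __iter__(self) -> Iterator[CostLineItem]:
        return iter(self.items)

    def __len__(self) -> int:
        return len(self.items)

    @classmethod
    def from_items(cls, items: Iterable[CostLineItem]) -> "CostLedger":
        return cls(items=tuple(items))

    def total(self) -> Decimal:
        return sum((it.amount for it in self.items), Decimal(0))

    def total_by(self, attr: str) -> dict[str, Decimal]:
        out: dict[str, Decimal] = {}
        for it in self.items:
            key = getattr(it, attr)
            out[key] = out.get(key, Decimal(0)) + it.amount
        return out

    def map_amounts(self, fn) -> "CostLedger":
        """New ledger with each item's amount replaced by fn(item)."""
        return CostLedger.from_items(replace(it, amount=fn(it)) for it in self.items)

    # -- delimited-text I/O ------------------------------------------------
    @classmethod
    def read_csv(cls, path) -> "CostLedger":
        """Read `period,amount,currency,year,category,phase,joint,cost_centre` CSV.

        The currency/year columns are carried in ``cost_centre``-independent
        metadata only insofar as conversion is applied separately; they are
        accepted and ignored if already converted.
        """
        df = pd.read_csv(path, dtype={"cost_centre": str}, keep_default_na=False)
        items = [
            CostLineItem(
                period=int(r["period"]),
                amount=Decimal(str(r["amount"])),
                category=str(r["category"]),
                phase=str(r["phase"]),
                joint=str(r["joint"]).strip().lower() in ("1", "true", "yes"),
                cost_centre=str(r.get("cost_centre", "")),
            )
            for _, r in df.iterrows()
        ]
        return cls.from_items(items)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "period": [it.period for it in self.items],
                "amount": [str(it.amount) for it in self.items],
                "category": [it.category for it in self.items],
                "phase": [it.phase for it in self.items],
                "joint": [int(it.joint) for it in self.items],
                "cost_centre": [it.cost_centre for it in self.items],
            }
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class AllocationRule:
    """Joint-cost and factorial-arm allocation shares.

    ``joint_share`` is the proportion of shared costs attributed to the women's-group
    intervention, either one global proportion or one per category;
    ``factorial_share`` is the proportion of implementation costs attributed to the
    women's-groups-only arm in a factorial trial (base 0.5).
    """

    joint_share: float | Mapping[str, float] = 1.0
    factorial_share: float = 0.5

    def __post_init__(self) -> None:
        shares = (
            self.joint_share.values()
            if isinstance(self.joint_share, Mapping)
            else [self.joint_share]
        )
        if any(not 0 <= s <= 1 for s in shares):
            raise ValueError("joint_share must lie in [0, 1]")
        if not 0 < self.factorial_share <= 1:
            raise ValueError("factorial_share must lie in (0, 1]")

    def share_for(self, category: str) -> float:
        if isinstance(self.joint_share, Mapping):
            if category not in self.joint_share:
                raise KeyError(f"no joint_share defined for category {category!r}")
            return self.joint_share[category]
        return self.joint_share


@dataclass(frozen=True)
class CurrencySpec:
    """Conversion to 2016 international dollars.

    Amounts are first inflated in local currency using ``deflator_series``
    (year -> index), then divided by ``ppp_factor`` (local currency units per
    international dollar in 2016). The order — inflate locally, then PPP-convert —
    is fixed.
    """

    source_currency: str
    source_year: int
    deflator_series: Mapping[int, float]
    ppp_factor: float
    target_year: int = 2016

    def __post_init__(self) -> None:
        if self.ppp_factor <= 0:
            raise ValueError("ppp_factor must be positive")
        if any(v <= 0 for v in self.deflator_series.values()):
            raise ValueError("deflator indices must be positive")


def convert_currency(amount: float, spec: CurrencySpec) -> float:
    """Convert a local-currency amount of ``spec.source_year`` into 2016 INT$."""
    for year in (spec.source_year, spec.target_year):
        if year not in spec.deflator_series:
            raise KeyError(f"deflator series missing year {year}")
    inflated = amount * spec.deflator_series[spec.target_year] / spec.deflator_series[spec.source_year]
    return inflated / spec.ppp_factor


def convert_ledger(ledger: CostLedger, spec: CurrencySpec) -> CostLedger:
    factor = Decimal(
        str(spec.deflator_series[spec.target_year] / spec.deflator_series[spec.source_year] / spec.ppp_factor)
    )
    return ledger.map_amounts(lambda it: it.amount * factor)


def allocate_joint_costs(ledger: CostLedger, rule: AllocationRule) -> CostLedger:
    """Scale every joint-flagged item by its category's joint share; others unchanged."""
    return ledger.map_amounts(
        lambda it: it.amount * Decimal(str(rule.share_for(it.category))) if it.joint else it.amount
    )


@dataclass(frozen=True)
class CostSummary:
    """Standardized costs for one trial (2016 INT$) plus the denominators used."""

    total_cost: float
    startup_cost: float
    implementation_cost: float
    annual_total_cost: float
    annual_implementation_cost: float
    cost_per_live_birth: float
    annual_cost_per_person: float
    annual_cost_per_group: float
    composition: Mapping[str, float] | None  # None when the ledger is empty
    # denominators, retained so reallocation can recompute consistently
    horizon_months: int = 0
    period_months: int = 0
    eff_live_births: float = 0.0
    eff_population: float = 0.0
    eff_groups: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.startup_cost + self.implementation_cost - self.total_cost) > 1e-6:
            raise ValueError("startup + implementation must equal total")
        if self.composition is not None:
            s = sum(self.composition.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"composition shares must sum to 1, got {s}")

    @classmethod
    def from_reported(
        cls, profile: TrialProfile, reported: TrialReportedResults
    ) -> "CostSummary":
        """Build a summary from published aggregates (no composition, no ledger)."""
        return cls(
            total_cost=reported.total_cost,
            startup_cost=reported.startup_cost,
            implementation_cost=reported.total_cost - reported.startup_cost,
            annual_total_cost=reported.annual_total_cost,
            annual_implementation_cost=reported.annual_implementation_cost,
            cost_per_live_birth=reported.cost_per_live_birth,
            annual_cost_per_person=reported.annual_cost_per_person,
            annual_cost_per_group=reported.annual_cost_per_group,
            composition=None,
            horizon_months=profile.ce_horizon_months,
            period_months=profile.intervention_period_months,
            eff_live_births=profile.effective_live_births(),
            eff_population=profile.effective_population(),
            eff_groups=profile.effective_n_groups(),
        )


def composition_shares(ledger: CostLedger) -> dict[str, float]:
    """Per-category share of total spending; shares sum to one."""
    total = ledger.total()
    if total == 0:
        raise ValueError("composition undefined for a zero-total ledger")
    by_cat = ledger.total_by("category")
    return {c: float(by_cat.get(c, Decimal(0)) / total) for c in CATEGORIES}


def summarize_costs(
    ledger: CostLedger,
    profile: TrialProfile,
    factorial_halving: bool = True,
) -> CostSummary:
    """Standardize a converted ledger into the cost summary.

    Annual figures annualize over the CE horizon (x 12 / horizon months) — the
    convention that reproduces the published annual totals and implementation
    costs. Unit-cost denominators are halved for factorial trials unless
    ``factorial_halving`` is disabled.
    """
    horizon, period = profile.ce_horizon_months, profile.intervention_period_months
    lb = profile.effective_live_births(factorial_halving)
    pop = profile.effective_population(factorial_halving)
    grp = profile.effective_n_groups(factorial_halving)
    if min(lb, pop, grp, horizon) <= 0:
        raise ValueError("denominators must be positive")

    by_phase = ledger.total_by("phase")
    startup = float(by_phase.get("startup", Decimal(0)))
    implementation = float(by_phase.get("implementation", Decimal(0)))
    total = startup + implementation
    annual_total = total * 12 / horizon
    return CostSummary(
        total_cost=total,
        startup_cost=startup,
        implementation_cost=implementation,
        annual_total_cost=annual_total,
        annual_implementation_cost=implementation * 12 / horizon,
        cost_per_live_birth=total / lb,
        annual_cost_per_person=annual_total / pop,
        annual_cost_per_group=annual_total / grp,
        composition=composition_shares(ledger) if total > 0 else None,
        horizon_months=horizon,
        period_months=period,
        eff_live_births=lb,
        eff_population=pop,
        eff_groups=grp,
    )


def apply_factorial_allocation(summary: CostSummary, factorial_share: float) -> CostSummary:
    """Re-attribute implementation costs to the women's-groups-only arm.

    The base summary carries 50% of implementation costs; scaling by
    ``factorial_share / 0.5`` moves to the requested share. Start-up costs are
    unchanged; total and derived figures are recomputed.
    """
    if not 0 < factorial_share <= 1:
        raise ValueError("factorial_share must lie in (0, 1]")
    impl_scale = factorial_share / 0.5
    impl = summary.implementation_cost * impl_scale
    total = summary.startup_cost + impl
    # scale derived figures multiplicatively so a 0.5 share is an exact identity
    total_scale = total / summary.total_cost if summary.total_cost else 0.0
    return dataclasses.replace(
        summary,
        implementation_cost=impl,
        total_cost=total,
        annual_total_cost=summary.annual_total_cost * total_scale,
        annual_implementation_cost=summary.annual_implementation_cost * impl_scale,
        cost_per_live_birth=summary.cost_per_live_birth * total_scale,
        annual_cost_per_person=summary.annual_cost_per_person * total_scale,
        annual_cost_per_group=summary.annual_cost_per_group * total_scale,
    )
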