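"""One-way deterministic sensitivity analysis on cost per life-year saved.

Each scenario changes exactly one parameter family of a per-trial base case and
recomputes the CER, everything else held fixed:

* ``add_maternal_lys`` — add maternal life-years saved to the denominator,
* ``startup_multiplier`` — scale start-up costs (e.g. 0.5 halves them),
* ``joint_share_delta`` — shift the joint-cost allocation share by +/- points,
* ``factorial_share`` — re-attribute implementation costs in factorial trials
  (base 50%),
* ``discount_rates`` — alternative (cost, life-year) discount rates.

A base case may be *ledger-backed* (a full line-item ledger with month stamps,
enabling joint-share and discount-rate recomputation) or *aggregate-only* (printed
totals, as for the published trials). Scenarios whose inputs a base case lacks
yield a not-applicable marker (None), never an exception — mirroring the N/A
cells of the published grid. Ledger-backed base cases discount costs to present
value at the base cost rate; aggregate bases use their printed totals as-is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from ._util import data_path
from .costing import AllocationRule, CostLedger, CostSummary, allocate_joint_costs, summarize_costs
from .effectiveness import DiscountSpec, discounted_life_expectancy, maternal_lys
from .fixtures import TRIAL_IDS, TrialProfile, load_all

NA = None  # not-applicable marker in grid cells


@dataclass(frozen=True)
class Scenario:
    """One named parameter override; exactly one transform per scenario."""

    name: str
    kind: str  # add_maternal_lys | startup_multiplier | joint_share_delta | factorial_share | discount_rates
    startup_multiplier: float | None = None
    joint_share_delta: float | None = None
    factorial_share: float | None = None
    discount_rates: tuple[float, float] | None = None  # (costs, life-years)

    def __post_init__(self) -> None:
        kinds = {
            "add_maternal_lys": None,
            "startup_multiplier": self.startup_multiplier,
            "joint_share_delta": self.joint_share_delta,
            "factorial_share": self.factorial_share,
            "discount_rates": self.discount_rates,
        }
        if self.kind not in kinds:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        set_params = [k for k, v in kinds.items() if v is not None]
        if self.kind != "add_maternal_lys" and set_params != [self.kind]:
            raise ValueError("exactly one transform parameter must be set, matching kind")
        if self.factorial_share is not None and not 0 < self.factorial_share <= 1:
            raise ValueError("factorial_share must lie in (0, 1]")


@dataclass(frozen=True)
class TrialBase:
    """Base case for one trial: costs, life-years and the inputs scenarios may need."""

    trial_id: str
    profile: TrialProfile
    cost: CostSummary
    lys: float  # discounted neonatal LYS at the base rate
    discount: DiscountSpec = field(default_factory=DiscountSpec)
    ledger: CostLedger | None = None  # raw (pre-joint-allocation) ledger, 2016 INT$
    joint_rule: AllocationRule | None = None
    maternal: dict | None = None  # {'or_maternal','baseline_deaths','age_at_death'} or {'maternal_lys'}


def pv_costs(ledger: CostLedger, rate: float) -> float:
    """Present value of ledger costs, continuous discounting by month stamp."""
    return sum(float(it.amount) * math.exp(-rate * it.period / 12.0) for it in ledger)


def _phase_costs(base: TrialBase, rate: float | None = None) -> tuple[float, float]:
    """(startup, implementation) costs; discounted PV for ledger-backed bases."""
    if base.ledger is not None:
        r = base.discount.rate_costs if rate is None else rate
        ledger = base.ledger
        if base.joint_rule is not None:
            ledger = allocate_joint_costs(ledger, base.joint_rule)
        su = sum(float(i.amount) * math.exp(-r * i.period / 12) for i in ledger if i.phase == "startup")
        im = sum(float(i.amount) * math.exp(-r * i.period / 12) for i in ledger if i.phase == "implementation")
        return su, im
    return base.cost.startup_cost, base.cost.implementation_cost


def base_cer(base: TrialBase) -> float:
    su, im = _phase_costs(base)
    return (su + im) / base.lys


def run_scenario(base: TrialBase, scenario: Scenario) -> float | None:
    """CER under one scenario, or None when the base case lacks the needed inputs."""
    su, im = _phase_costs(base)

    if scenario.kind == "startup_multiplier":
        return (scenario.startup_multiplier * su + im) / base.lys

    if scenario.kind == "factorial_share":
        if not base.profile.factorial:
            return NA
        return (su + im * scenario.factorial_share / 0.5) / base.lys

    if scenario.kind == "add_maternal_lys":
        if base.maternal is None:
            return NA
        m = base.maternal
        extra = (
            m["maternal_lys"]
            if "maternal_lys" in m
            else maternal_lys(
                m["or_maternal"], m["baseline_deaths"], m["age_at_death"], spec=base.discount
            )
        )
        return (su + im) / (base.lys + extra)

    if scenario.kind == "joint_share_delta":
        if base.ledger is None or base.joint_rule is None:
            return NA
        rule = base.joint_rule
        if isinstance(rule.joint_share, dict):
            shifted = {c: min(1.0, max(0.0, s + scenario.joint_share_delta)) for c, s in rule.joint_share.items()}
        else:
            shifted = min(1.0, max(0.0, rule.joint_share + scenario.joint_share_delta))
        new_base = TrialBase(
            trial_id=base.trial_id, profile=base.profile, cost=base.cost, lys=base.lys,
            discount=base.discount, ledger=base.ledger,
            joint_rule=AllocationRule(joint_share=shifted, factorial_share=rule.factorial_share),
            maternal=base.maternal,
        )
        su2, im2 = _phase_costs(new_base)
        return (su2 + im2) / base.lys

    if scenario.kind == "discount_rates":
        if base.ledger is None:
            return NA
        rc, rl = scenario.discount_rates
        su2, im2 = _phase_costs(base, rate=rc)
        scale = discounted_life_expectancy(rl, base.discount.standard_le) if rl > 0 else base.discount.standard_le
        base_scale = discounted_life_expectancy(base.discount.rate_lys, base.discount.standard_le)
        return (su2 + im2) / (base.lys * scale / base_scale)

    raise ValueError(f"unknown scenario kind {scenario.kind!r}")


@dataclass(frozen=True)
class SensitivityGrid:
    """Scenario x trial grid of CERs; base row first; mean % change per scenario."""

    table: pd.DataFrame  # rows: 'base_case' + scenario names; NaN marks N/A cells
    mean_pct_change: dict[str, float]  # over applicable trials, vs the base row

    def to_csv(self, path) -> None:
        self.table.to_csv(path, na_rep="N/A")


def run_grid(bases: Sequence[TrialBase], scenarios: Sequence[Scenario]) -> SensitivityGrid:
    cols = [b.trial_id for b in bases]
    base_row = {b.trial_id: base_cer(b) for b in bases}
    rows = {"base_case": base_row}
    mean_change: dict[str, float] = {}
    for sc in scenarios:
        row, changes = {}, []
        for b in bases:
            val = run_scenario(b, sc)
            row[b.trial_id] = np.nan if val is NA else val
            if val is not NA:
                changes.append((val - base_row[b.trial_id]) / base_row[b.trial_id])
        rows[sc.name] = row
        mean_change[sc.name] = float(np.mean(changes)) if changes else float("nan")
    table = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    return SensitivityGrid(table=table, mean_pct_change=mean_change)


def standard_scenarios() -> list[Scenario]:
    """The published one-way grid: maternal LYS, start-up halving, joint-share
    shifts, factorial bounds and alternative discount rates."""
    return [
        Scenario("add_maternal_lys", "add_maternal_lys"),
        Scenario("startup_50pct", "startup_multiplier", startup_multiplier=0.5),
        Scenario("joint_minus_10pts", "joint_share_delta", joint_share_delta=-0.10),
        Scenario("joint_plus_10pts", "joint_share_delta", joint_share_delta=+0.10),
        Scenario("factorial_33pct", "factorial_share", factorial_share=0.33),
        Scenario("factorial_75pct", "factorial_share", factorial_share=0.75),
        Scenario("discount_0_0", "discount_rates", discount_rates=(0.0, 0.0)),
        Scenario("discount_6_3", "discount_rates", discount_rates=(0.06, 0.03)),
    ]


def fixture_bases() -> list[TrialBase]:
    """Aggregate-only base cases for the six published trials."""
    bases = []
    for tid, (profile, reported) in load_all().items():
        bases.append(
            TrialBase(
                trial_id=tid,
                profile=profile,
                cost=CostSummary.from_reported(profile, reported),
                lys=reported.neonatal_lys,
            )
        )
    return bases


def load_reported_grid() -> dict:
    """Published sensitivity grid (regression fixture, stored as printed)."""
    return yaml.safe_load(data_path("sensitivity_reported.yaml").read_text())
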