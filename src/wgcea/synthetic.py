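"""Synthetic trial generator: cost ledgers and surveillance outcomes.

Emulates the data structures the pipeline consumes so it can be exercised and
calibrated end-to-end without any external data:

* a monthly cost ledger with a start-up phase followed by an implementation
  phase, one line item per category per month, lognormal amounts around a
  category budget split (defaults: 65% staff / 2% materials / 18% other
  recurrent / 15% capital, matching the composition observed across the trials);
* surveillance outcomes: Poisson live births per arm from a population and a
  crude birth rate, binomial neonatal deaths at the control NMR and at the
  intervention NMR reduced by the effect size (default 33%).

A single seed drives independent substreams for the ledger and the outcomes, so
either can be regenerated in isolation; identical seeds give identical output.
:func:`end_to_end_recovery` pushes generated data through costing ->
effectiveness -> CER and reports the relative error against the analytic truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal

import numpy as np

from .cea import cost_effectiveness_ratio
from .costing import CATEGORIES, CostLedger, CostLineItem, summarize_costs
from .effectiveness import DiscountSpec, discounted_life_expectancy
from .fixtures import TrialProfile

DEFAULT_MIX = {"staff": 0.65, "materials": 0.02, "other_recurrent": 0.18, "capital": 0.15}


@dataclass(frozen=True)
class SyntheticTrialSpec:
    """Parameters of one synthetic trial; defaults sit mid-range of the six trials."""

    seed: int = 0
    months_startup: int = 9
    months_implementation: int = 36
    monthly_budget: float = 40_000.0  # 2016 INT$
    category_mix: dict = field(default_factory=lambda: dict(DEFAULT_MIX))
    joint_fraction: float = 0.35
    population: int = 250_000
    crude_birth_rate: float = 30.0  # births per 1000 person-years
    nmr_control: float = 40.0  # neonatal deaths per 1000 live births
    effect: float = 0.33  # proportional NMR reduction in the intervention arm
    noise_cv: float = 0.2  # coefficient of variation of line-item amounts

    def __post_init__(self) -> None:
        if abs(sum(self.category_mix.values()) - 1.0) > 1e-9:
            raise ValueError("category_mix must sum to 1")
        if not 0 <= self.effect <= 1 or not 0 <= self.joint_fraction <= 1:
            raise ValueError("effect and joint_fraction must lie in [0, 1]")
        for name in ("monthly_budget", "population", "crude_birth_rate", "nmr_control"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")

    @property
    def months_total(self) -> int:
        return self.months_startup + self.months_implementation

    def profile(self) -> TrialProfile:
        """Matching trial profile (horizon = full project span, full surveillance)."""
        years = self.months_implementation / 12.0
        expected_births = self.population * self.crude_birth_rate / 1000.0 * years
        return TrialProfile(
            trial_id="synthetic",
            intervention_period_months=self.months_implementation,
            ce_horizon_months=self.months_total,
            population=self.population,
            live_births=max(1, int(round(expected_births))),
            n_groups=max(1, self.population // 600),
            meetings_per_group=20,
            coverage=0.35,
            surveillance_fraction=1.0,
            factorial=False,
            gdp_pc_ppp=3000.0,
        )


def _rngs(spec: SyntheticTrialSpec) -> tuple[np.random.Generator, np.random.Generator]:
    ss = np.random.SeedSequence(spec.seed)
    ledger_ss, outcome_ss = ss.spawn(2)
    return np.random.default_rng(ledger_ss), np.random.default_rng(outcome_ss)


def generate_ledger(spec: SyntheticTrialSpec) -> CostLedger:
    """One line item per category per month; lognormal noise around budget x mix.

    At ``noise_cv = 0`` amounts are exactly the category means, so category totals
    equal budget x mix x months. Months before ``months_startup`` are tagged
    start-up. Deterministic given the seed.
    """
    rng, _ = _rngs(spec)
    cv = spec.noise_cv
    sigma2 = np.log1p(cv * cv)
    sigma = float(np.sqrt(sigma2))
    items = []
    for month in range(spec.months_total):
        phase = "startup" if month < spec.months_startup else "implementation"
        for cat in CATEGORIES:
            mean = spec.monthly_budget * spec.category_mix.get(cat, 0.0)
            if mean == 0.0:
                continue
            if cv == 0.0:
                amount = mean
            else:
                # lognormal parameterized to mean `mean` and CV `cv`
                mu = np.log(mean) - sigma2 / 2.0
                amount = float(rng.lognormal(mu, sigma))
            joint = bool(rng.random() < spec.joint_fraction)
            items.append(
                CostLineItem(
                    period=month,
                    amount=Decimal(f"{amount:.2f}"),
                    category=cat,
                    phase=phase,
                    joint=joint,
                    cost_centre=f"synthetic/{cat}",
                )
            )
    return CostLedger.from_items(items)


@dataclass(frozen=True)
class SyntheticOutcomes:
    births_control: int
    births_intervention: int
    deaths_control: int
    deaths_intervention: int


def generate_outcomes(spec: SyntheticTrialSpec) -> SyntheticOutcomes:
    """Poisson births per arm, binomial neonatal deaths at the arm-specific NMR."""
    _, rng = _rngs(spec)
    years = spec.months_implementation / 12.0
    lam = spec.population * spec.crude_birth_rate / 1000.0 * years
    births_c = int(rng.poisson(lam))
    births_i = int(rng.poisson(lam))
    p_c = spec.nmr_control / 1000.0
    p_i = p_c * (1.0 - spec.effect)
    deaths_c = int(rng.binomial(births_c, p_c)) if births_c else 0
    deaths_i = int(rng.binomial(births_i, p_i)) if births_i else 0
    return SyntheticOutcomes(births_c, births_i, deaths_c, deaths_i)


def expected_deaths_averted(spec: SyntheticTrialSpec) -> float:
    """Analytic expectation: E[births] x NMR/1000 x effect."""
    years = spec.months_implementation / 12.0
    births = spec.population * spec.crude_birth_rate / 1000.0 * years
    return births * spec.nmr_control / 1000.0 * spec.effect


def true_cer(spec: SyntheticTrialSpec, discount: DiscountSpec = DiscountSpec()) -> float:
    """Ground-truth CER: expected total cost over expected discounted LYS."""
    total = spec.monthly_budget * spec.months_total
    dle = discounted_life_expectancy(discount.rate_lys, discount.standard_le)
    return total / (expected_deaths_averted(spec) * dle)


@dataclass(frozen=True)
class RecoveryReport:
    estimated_cer: float
    true_cer: float
    deaths_averted_estimate: float

    @property
    def relative_error(self) -> float:
        return (self.estimated_cer - self.true_cer) / self.true_cer


def end_to_end_recovery(
    spec: SyntheticTrialSpec,
    discount: DiscountSpec = DiscountSpec(),
    expected_counts: bool = False,
) -> RecoveryReport:
    """Run ledger -> costing -> effectiveness -> CER and compare with the truth.

    With ``expected_counts`` the analytic expectations replace the sampled
    outcomes (and the ledger should be noiseless), which must recover the true
    CER to numerical precision.
    """
    ledger = generate_ledger(spec)
    summary = summarize_costs(ledger, spec.profile())
    if expected_counts:
        averted = expected_deaths_averted(spec)
    else:
        out = generate_outcomes(spec)
        rate_c = out.deaths_control / out.births_control
        rate_i = out.deaths_intervention / out.births_intervention
        averted = out.births_intervention * (rate_c - rate_i)
    dle = discounted_life_expectancy(discount.rate_lys, discount.standard_le)
    est = cost_effectiveness_ratio(summary.total_cost, averted * dle)
    return RecoveryReport(
        estimated_cer=est,
        true_cer=true_cer(spec, discount),
        deaths_averted_estimate=averted,
    )
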