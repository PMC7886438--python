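"""Reference data for the six women's-group trials.

Each trial ships as one YAML file holding (a) its design parameters — intervention
period, cost-effectiveness horizon, population, live births, number of groups,
coverage — and (b) the published cost and effectiveness results in 2016
international dollars. Published values are stored exactly as printed and are
never recomputed on load; :func:`consistency_report` recomputes every derivable
quantity and flags disagreements instead of silently overwriting anything.

The two Malawi trials used a factorial design testing a second intervention in
half the area: their costs refer to the women's-groups-only arm, so unit-cost
denominators (population, live births, groups) are halved relative to the
full-area figures stored here. MaiKhanda additionally kept only ~1/11 of the
area under birth/death surveillance; its ``surveillance_fraction`` records that.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

from ._util import data_path, round_half_away

TRIAL_IDS = ("India", "Nepal", "BangladeshI", "BangladeshII", "MaiMwana", "MaiKhanda")

_FILES = {
    "India": "india.yaml",
    "Nepal": "nepal.yaml",
    "BangladeshI": "bangladesh1.yaml",
    "BangladeshII": "bangladesh2.yaml",
    "MaiMwana": "maimwana.yaml",
    "MaiKhanda": "maikhanda.yaml",
}


class UnknownTrialError(KeyError):
    """Raised for trial ids outside the six supported trials (e.g. the excluded urban Mumbai trial)."""


@dataclass(frozen=True)
class TrialProfile:
    """Design parameters of one trial (full-area figures as published)."""

    trial_id: str
    intervention_period_months: int
    ce_horizon_months: int
    population: int
    live_births: int
    n_groups: int
    meetings_per_group: int
    coverage: float  # share of pregnant women who ever attended a group
    surveillance_fraction: float  # share of area under birth/death surveillance
    factorial: bool
    gdp_pc_ppp: float  # 2016 INT$ per person-year

    def __post_init__(self) -> None:
        if not self.intervention_period_months <= self.ce_horizon_months:
            raise ValueError("intervention period must not exceed the CE horizon")
        if not 0 < self.coverage <= 1:
            raise ValueError("coverage must be in (0, 1]")
        if not 0 < self.surveillance_fraction <= 1:
            raise ValueError("surveillance_fraction must be in (0, 1]")
        for field in ("population", "live_births", "n_groups"):
            if getattr(self, field) <= 0:
                raise ValueError(f"{field} must be positive")

    def _eff(self, full: float, halve: bool) -> float:
        return full / 2 if (halve and self.factorial) else full

    def effective_population(self, factorial_halving: bool = True) -> float:
        return self._eff(self.population, factorial_halving)

    def effective_live_births(self, factorial_halving: bool = True) -> float:
        return self._eff(self.live_births, factorial_halving)

    def effective_n_groups(self, factorial_halving: bool = True) -> float:
        return self._eff(self.n_groups, factorial_halving)


@dataclass(frozen=True)
class TrialReportedResults:
    """Published results, stored exactly as printed (2016 INT$)."""

    total_cost: float
    startup_cost: float
    annual_total_cost: float
    annual_implementation_cost: float
    cost_per_live_birth: float
    annual_cost_per_group: float
    annual_cost_per_person: float
    deaths_averted: float
    neonatal_lys: float
    cer: float
    joint_share_rule: tuple[float, float] | None = None  # base joint-allocation share range

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and v < 0:
                raise ValueError(f"{f.name} must be non-negative")
        if self.startup_cost > self.total_cost:
            raise ValueError("startup_cost cannot exceed total_cost")


def load_fixture(trial_id: str) -> tuple[TrialProfile, TrialReportedResults]:
    """Load one trial's profile and published results from the packaged YAML.

    Raises :class:`UnknownTrialError` for any id outside the six trials.
    """
    try:
        fname = _FILES[trial_id]
    except KeyError:
        raise UnknownTrialError(
            f"unknown trial {trial_id!r}; supported: {', '.join(TRIAL_IDS)}"
        ) from None
    raw = yaml.safe_load(data_path("trials", fname).read_text())
    prof = raw["profile"]
    profile = TrialProfile(trial_id=raw["trial_id"], **prof)
    rep = dict(raw["reported"])
    rule = rep.get("joint_share_rule")
    rep["joint_share_rule"] = tuple(rule) if rule is not None else None
    reported = TrialReportedResults(**rep)
    return profile, reported


def load_all() -> dict[str, tuple[TrialProfile, TrialReportedResults]]:
    return {tid: load_fixture(tid) for tid in TRIAL_IDS}


@dataclass(frozen=True)
class Discrepancy:
    """One consistency-check record: a printed value versus its recomputation."""

    trial_id: str
    field: str
    printed: float
    recomputed: float
    tolerance: float  # one unit in the last printed digit

    @property
    def flagged(self) -> bool:
        return abs(round_half_away(self.recomputed, self._ndigits()) - self.printed) > self.tolerance

    def _ndigits(self) -> int:
        return 1 if self.tolerance < 1 else 0


def consistency_report(
    profile: TrialProfile, reported: TrialReportedResults
) -> list[Discrepancy]:
    """Recompute every derivable published quantity and flag disagreements.

    Annualization divides by the CE horizon (the convention that reproduces the
    published annual figures for all six trials); unit costs use
    factorial-halved denominators. Returns all records, flagged or not, so the
    caller sees what was checked. Fixtures are never mutated.
    """
    impl = reported.total_cost - reported.startup_cost
    lb = profile.effective_live_births()
    pop = profile.effective_population()
    grp = profile.effective_n_groups()
    annual = reported.total_cost * 12 / profile.ce_horizon_months
    checks = [
        ("annual_total_cost", reported.annual_total_cost, annual, 1.0),
        (
            "annual_implementation_cost",
            reported.annual_implementation_cost,
            impl * 12 / profile.ce_horizon_months,
            1.0,
        ),
        ("cost_per_live_birth", reported.cost_per_live_birth, reported.total_cost / lb, 1.0),
        ("annual_cost_per_group", reported.annual_cost_per_group, annual / grp, 1.0),
        ("annual_cost_per_person", reported.annual_cost_per_person, annual / pop, 0.1),
        ("cer", reported.cer, reported.total_cost / reported.neonatal_lys, 1.0),
    ]
    return [Discrepancy(profile.trial_id, f, p, r, tol) for f, p, r, tol in checks]
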