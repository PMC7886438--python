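"""National scale-up projection: cost, affordability and neonatal lives saved.

Scale-up assumes one year of delivery to a country's whole rural population at a
constant cost per person-year taken from the trial in that context (the screen
found no usable evidence of economies of scale). Lives saved apply a 33%
reduction in neonatal mortality at full trial effectiveness, with a lower bound
attenuating the effect by 30% for programmatic delivery. Affordability expresses
the annual cost as a share of total health expenditure (THE), government health
expenditure (GHE) and GDP.

Country population and expenditure inputs are user-supplied via
:class:`ScaleUpScenario` (YAML config supported); the published projections ship
as a regression fixture via :func:`load_reported_scaleup`.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from ._util import data_path, round_half_away

DEFAULT_EFFECT = 0.33  # proportional NMR reduction at full trial effectiveness
DEFAULT_ATTENUATION = 0.30  # proportional loss of effect at scale


@dataclass(frozen=True)
class ScaleUpScenario:
    country: str
    rural_population: float  # persons reached at coverage 1.0
    cost_per_person_year: float  # 2016 INT$, constant at scale
    rural_live_births: float | None = None  # per year
    nmr: float | None = None  # neonatal deaths per 1000 live births
    effect: float = DEFAULT_EFFECT
    attenuation: float = DEFAULT_ATTENUATION
    coverage_fraction: float = 1.0
    total_health_expenditure: float | None = None  # $ per year
    government_health_expenditure: float | None = None
    gdp: float | None = None
    national_neonatal_deaths: float | None = None

    def __post_init__(self) -> None:
        for name in ("effect", "attenuation", "coverage_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.rural_population < 0 or self.cost_per_person_year < 0:
            raise ValueError("population and unit cost must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "ScaleUpScenario":
        return cls(**yaml.safe_load(open(path)))


@dataclass(frozen=True)
class ScaleUpResult:
    country: str
    annual_cost: float
    pct_the: float | None
    pct_ghe: float | None
    pct_gdp: float | None
    lives_saved_full: float
    lives_saved_attenuated: float
    pct_burden_full: float | None
    pct_burden_attenuated: float | None


def scale_up_cost(scenario: ScaleUpScenario) -> float:
    """Annual cost of delivery: unit cost x rural population x coverage fraction."""
    return scenario.cost_per_person_year * scenario.rural_population * scenario.coverage_fraction


def affordability(annual_cost: float, scenario: ScaleUpScenario) -> tuple[float, float, float]:
    """(%, %, %) of THE, GHE and GDP, each rounded to 2 decimals."""
    out = []
    for denom in (
        scenario.total_health_expenditure,
        scenario.government_health_expenditure,
        scenario.gdp,
    ):
        if denom is None or denom <= 0:
            raise ValueError("expenditure denominators must be positive")
        out.append(round_half_away(100 * annual_cost / denom, 2))
    return tuple(out)


def attenuate(lives_full: float, attenuation: float = DEFAULT_ATTENUATION) -> float:
    """Lower-bound lives saved: full x (1 - attenuation), rounded half away from zero."""
    return round_half_away(lives_full * (1 - attenuation))


def lives_saved(scenario: ScaleUpScenario) -> ScaleUpResult:
    """Project neonatal lives saved at full and attenuated effectiveness.

    full = births x (NMR/1000) x effect x coverage; attenuated = full x (1 - attenuation).
    Burden shares divide by national neonatal deaths when supplied.
    """
    if scenario.rural_live_births is None or scenario.nmr is None:
        raise ValueError("rural_live_births and nmr are required")
    full = (
        scenario.rural_live_births
        * scenario.nmr
        / 1000.0
        * scenario.effect
        * scenario.coverage_fraction
    )
    att = full * (1 - scenario.attenuation)
    cost = scale_up_cost(scenario)
    try:
        pct_the, pct_ghe, pct_gdp = affordability(cost, scenario)
    except ValueError:
        pct_the = pct_ghe = pct_gdp = None
    burden = scenario.national_neonatal_deaths
    return ScaleUpResult(
        country=scenario.country,
        annual_cost=cost,
        pct_the=pct_the,
        pct_ghe=pct_ghe,
        pct_gdp=pct_gdp,
        lives_saved_full=full,
        lives_saved_attenuated=att,
        pct_burden_full=100 * full / burden if burden else None,
        pct_burden_attenuated=100 * att / burden if burden else None,
    )


def load_reported_scaleup() -> dict:
    """Published scale-up projections (regression fixture, stored as printed)."""
    return yaml.safe_load(data_path("scaleup_reported.yaml").read_text())
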