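"""Cost-effectiveness ratios and income-based threshold classification.

The CER is average cost per neonatal life-year saved versus current practice (the
control arms received no incremental intervention cost, so the ratio is computed
against a zero-cost comparator). Classification follows the WHO income-based
convention: *very cost-effective* below 1x GDP per capita per LYS, *cost-effective*
below 3x, otherwise not cost-effective — strict inequalities. A stricter
supply-side flag marks CERs below 60% of GDP per capita.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._util import round_half_away

VERY_COST_EFFECTIVE = "very_cost_effective"
COST_EFFECTIVE = "cost_effective"
NOT_COST_EFFECTIVE = "not_cost_effective"

SUPPLY_SIDE_SHARE = 0.60


@dataclass(frozen=True)
class CERResult:
    cer: float  # 2016 INT$ per LYS
    gdp_pc: float
    ratio_to_gdp: float  # cer / gdp_pc
    who_class: str
    supply_side_flag: bool  # True when cer < 0.60 x GDP pc

    @property
    def pct_of_gdp(self) -> int:
        """Ratio to GDP per capita as an integer percentage (reporting convention)."""
        return int(round_half_away(100 * self.ratio_to_gdp))


def cost_effectiveness_ratio(total_cost: float, lys: float) -> float:
    """Average cost per life-year saved; unrounded (round only at reporting)."""
    if lys <= 0:
        raise ValueError("lys must be positive")
    if total_cost < 0:
        raise ValueError("total_cost must be non-negative")
    return total_cost / lys


def classify_threshold(cer: float, gdp_pc: float) -> CERResult:
    """Classify a CER against WHO income-based and supply-side thresholds."""
    if gdp_pc <= 0:
        raise ValueError("gdp_pc must be positive")
    if cer < gdp_pc:
        who = VERY_COST_EFFECTIVE
    elif cer < 3 * gdp_pc:
        who = COST_EFFECTIVE
    else:
        who = NOT_COST_EFFECTIVE
    return CERResult(
        cer=cer,
        gdp_pc=gdp_pc,
        ratio_to_gdp=cer / gdp_pc,
        who_class=who,
        supply_side_flag=cer < SUPPLY_SIDE_SHARE * gdp_pc,
    )
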