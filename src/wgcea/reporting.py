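"""Table emission: reproduce the published result tables from packaged fixtures.

Writes delimited-text tables mirroring the published layout — cost description,
unit costs, effectiveness/cost-effectiveness, scale-up lives saved (attenuated
column recomputed from the full-effect column), and the recomputable rows of the
one-way sensitivity grid — plus the consistency report contrasting every
printed value with its recomputation. Monetary columns are 2016 INT$; rounding
is applied only at emission.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from ._util import round_half_away
from .cea import classify_threshold
from .fixtures import TRIAL_IDS, consistency_report, load_all
from .scaleup import attenuate, load_reported_scaleup
from .sensitivity import fixture_bases, run_grid, standard_scenarios

MONEY_TAG = "2016 INT$"


def reproduce_tables(outdir) -> dict[str, pd.DataFrame]:
    """Emit the reproduction tables into ``outdir``; returns {name: DataFrame}."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fixtures = load_all()

    cost_rows = {
        f"Total cost ({MONEY_TAG})": "total_cost",
        f"Start-up cost ({MONEY_TAG})": "startup_cost",
        f"Annual total cost ({MONEY_TAG})": "annual_total_cost",
        f"Annual cost of implementation ({MONEY_TAG})": "annual_implementation_cost",
    }
    costs = pd.DataFrame(
        {tid: {label: getattr(fixtures[tid][1], attr) for label, attr in cost_rows.items()}
         for tid in TRIAL_IDS}
    )
    costs["Mean"] = [round_half_away(v) for v in costs.mean(axis=1)]

    unit_rows = {
        f"Cost per live birth ({MONEY_TAG})": "cost_per_live_birth",
        f"Annual cost per group ({MONEY_TAG})": "annual_cost_per_group",
        f"Annual cost per person ({MONEY_TAG})": "annual_cost_per_person",
    }
    units = pd.DataFrame(
        {tid: {label: getattr(fixtures[tid][1], attr) for label, attr in unit_rows.items()}
         for tid in TRIAL_IDS}
    )

    cea_rows = {}
    for tid in TRIAL_IDS:
        profile, reported = fixtures[tid]
        res = classify_threshold(reported.cer, profile.gdp_pc_ppp)
        cea_rows[tid] = {
            "Neonatal deaths averted": reported.deaths_averted,
            "Neonatal LYS (discounted 3%)": reported.neonatal_lys,
            f"Cost per neonatal LYS ({MONEY_TAG})": reported.cer,
            f"GDP per capita, PPP 2016 ({MONEY_TAG})": profile.gdp_pc_ppp,
            "WHO class": res.who_class,
            "% of GDP per capita": res.pct_of_gdp,
        }
    cea = pd.DataFrame(cea_rows)

    scale = load_reported_scaleup()
    lives = pd.DataFrame(
        {
            c: {
                "Lives saved, full effectiveness": d["lives_saved_full"],
                "Lives saved, 30% loss at scale (recomputed)": attenuate(d["lives_saved_full"]),
            }
            for c, d in scale["countries"].items()
        }
    )

    grid = run_grid(fixture_bases(), standard_scenarios())
    sens = grid.table.map(lambda v: round_half_away(v) if v == v else v)

    report = pd.DataFrame(
        [
            {
                "trial": d.trial_id,
                "field": d.field,
                "printed": d.printed,
                "recomputed": d.recomputed,
                "flagged": d.flagged,
            }
            for tid in TRIAL_IDS
            for d in consistency_report(*fixtures[tid])
        ]
    )

    tables = {
        "table_costs": costs,
        "table_unit_costs": units,
        "table_cea": cea,
        "table_scaleup_lives": lives,
        "table_sensitivity": sens,
        "consistency_report": report,
    }
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", na_rep="N/A")
    return tables
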