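# Methods

This note records the modelling conventions, parameter choices and numerical
decisions behind `wgcea`, and what the synthetic-data tests do and do not show.

## Costing model

A ledger line item carries a 0-based month index, a non-negative amount, a
category from {staff, materials, other_recurrent, capital}, a phase from
{startup, implementation} and a joint-cost flag. Amounts are stored as exact
decimals so ledger sums carry no floating drift; summaries are floats.

**Currency.** Conversion to 2016 INT$ inflates in local currency with a
user-supplied deflator series and then divides by the 2016 PPP factor. The
order (inflate locally, then PPP-convert) is the standard convention in
multi-country costing; it is fixed but the spec object makes both series
explicit so any alternative can be expressed by pre-transforming them.

**Joint costs.** Items flagged joint are scaled by the allocation share
(global or per category) before any aggregation. Allocation at share 1.0 is an
identity; total cost is monotone and linear in the share.

**Annualization.** Both annual total cost and annual implementation cost are
amount × 12 / CE-horizon months. Dividing implementation cost by the horizon
(rather than the shorter intervention period) is the convention that exactly
reproduces all six trials' published annual implementation costs (e.g. India
(797,212 − 308,810) × 12/49 = 119,609; MaiKhanda 2,620,155 × 12/48 = 655,039);
the package adopts it throughout and the consistency report verifies it per
trial.

**Factorial trials.** The two Malawi trials tested a second intervention in a
factorial design; costs and effects refer to the women's-groups-only arm, so
unit-cost denominators (population, live births, groups) are half the full-area
figures. This is the only convention that reproduces the published unit costs
(MaiKhanda: 3,064,842 / 50,000 = 61 $/live birth). Re-attributing
implementation costs at a share s scales them by s/0.5 with start-up costs
unchanged — again the only rule consistent with the published 33%/75% bounds
(CERs 202/406 for MaiKhanda). One published value resists every convention:
MaiMwana's 193 $/live birth implies a denominator (~4,687) matching neither the
full (9,174) nor the half (4,587) area; it is stored as printed and flagged by
the consistency report, never silently corrected.

**Degenerate inputs.** An empty ledger summarizes to zero costs with
composition marked undefined (None) rather than raising; zero unit-cost
denominators raise.

## Life-years saved

Discounting is continuous: DLE(r, L) = (1 − e^(−rL))/r, with the limit L at
r = 0, computed via `expm1` for precision at small rates. Continuous
discounting is chosen because DLE(0.03, 86) = 30.806 ≈ 30.81, the multiplier
used throughout the published analysis, whereas an annual-annuity formula gives
29.98. A quadrature oracle (∫₀ᴸ e^(−rt) dt) confirms the closed form to 1e−9
across r ∈ [0, 0.10].

Surveillance adjustment divides recorded deaths by the surveyed fraction of the
area (MaiKhanda: fraction 1/11, i.e. the ×11 inflation). Maternal LYS
(sensitivity only) convert an odds ratio to deaths averted via the rare-event
approximation (deaths × (1 − OR)) and value them at the discounted residual
life expectancy for the mean age at maternal death (26–30 years). The default
residual-LE table shipped with the package is a **synthetic** linear stand-in
(residual = 86 − age, `life_table_synthetic.csv`); any `age,residual_le` CSV
can be substituted, and no published result reproduced by the package depends
on the default table.

Published per-trial LYS differ by up to a few units from rounded-deaths × 30.81
(the unrounded death counts were not published); fixtures keep the printed LYS
and tests tolerate one unit in the last printed digit where this matters.

## Thresholds

WHO income-based classes use strict inequalities (very cost-effective < 1× GDP
per capita, cost-effective < 3×); a CER exactly equal to GDP per capita is
therefore "cost-effective". The supply-side flag marks CER < 60% of GDP per
capita. The comparator is current practice with zero incremental cost, so the
ratio is an average rather than incremental CER.

## Variation screen

Pearson r is computed from the product-moment definition; the two-sided
p-value uses the exact t distribution on n − 2 degrees of freedom, which
matters at n = 6. No multiple-testing correction is applied (nine descriptive
pairs, reported together). Scale and intensity variables default to
factorial-halved denominators — the convention under which the published
correlations (−0.54 for births vs unit cost, −0.09 for groups vs unit cost)
reproduce exactly; a switch exposes full-area denominators.

## Scale-up

Cost scales linearly in population and coverage at a constant cost per
person-year; lives saved = births × NMR/1000 × effect × coverage, with the
attenuated bound = full × 0.7 at the default 30% loss. Lives are rounded half
away from zero after attenuation (2,527 × 0.7 = 1,768.9 → 1,769). Published
country projections ship as a regression fixture; the underlying rural
population and expenditure denominators are scenario inputs supplied by the
user, since they are not part of the package's own data. The published
four-country full-effect total exceeds the sum of its printed rows by one unit
(unrounded components); the attenuated total (42,858) is exact.

## Sensitivity engine

A base case is either aggregate-only (published totals + LYS) or ledger-backed
(line items with month stamps). Exactly one parameter family changes per
scenario; inapplicable combinations return an N/A marker, mirroring the
published grid (no maternal inputs for Bangladesh I; joint-share rule undefined
for Nepal; factorial shares only for the Malawi trials). Joint-share and
discount-rate scenarios need the ledger (joint-cost totals and cost
time-profiles are not recoverable from printed aggregates), so they are N/A on
the published base cases and fully recomputed on ledger-backed ones; the
published rows are retained as fixtures for qualitative comparison. For
ledger-backed bases, costs are discounted to present value continuously by
month stamp at the base cost rate; removing discounting on a ledger whose
costs all fall at month zero changes the CER by exactly 1 − 30.81/86 = 64.2%,
and time-spread costs attenuate this toward the low-60s, as the grid's
qualitative check asserts.

## Synthetic-data generator

The generator emulates (a) a trial ledger — one line item per category per
month, lognormal amounts around a monthly budget split 65/2/18/15 across
staff/materials/other-recurrent/capital (the composition observed across the
trials), a start-up phase of 9 months before 36 implementation months, joint
flags at probability 0.35 (within the trials' 25–40% base allocation rules) —
and (b) surveillance outcomes: Poisson births per arm from 250,000 persons at a
crude birth rate of 30/1000 person-years, binomial neonatal deaths at a control
NMR of 40/1000 live births and a 33% reduction in the intervention arm. The
monthly budget of $40,000 puts the total (~$1.8M) mid-range of the six trials.
A single seed spawns independent substreams for ledger and outcomes, so either
regenerates alone; identical seeds give byte-identical output.

At these sizes binomial sampling error alone puts the median absolute relative
error of the end-to-end recovered CER just under 10% (the test asserts <10%
over 200 seeds); with noise off and analytic expectations substituted the
pipeline recovers the true CER to 1e−9, confirming the deterministic path is
exact. What passing these tests shows is that the pipeline's arithmetic is
correct under the generator's assumptions; what it does not show is robustness
to features of real trial data the generator omits — cluster-level random
effects and intraclass correlation, cost seasonality and lumpy capital
purchases, misclassified phases, or coverage-dependent effectiveness.

## Numerical conventions

Internal computation is unrounded; reporting rounds half away from zero to the
precision of the published tables (Python's banker's rounding would disagree on
half-unit cases such as 766,210.5). The consistency report flags a recomputed
value only when it differs from the printed one by more than one unit in the
last printed digit. Money in ledgers is exact decimal; everything downstream is
float64.

## Problem sizes

The test suite runs in a few seconds: the reference data are six trials, the
Monte Carlo checks use 50–200 seeds of the generator (each a 45-month ledger
and two binomial arms), and property tests cap at tens of examples. These sizes
were chosen as comfortably sufficient for the 3-standard-error and median-error
bands being asserted.

## Known limitations

- Provider perspective only; no societal costs, no time costs of participants.
- No probabilistic sensitivity analysis or CEACs: the published inputs carry no
  sampling-uncertainty estimates to propagate.
- The step-down costing that produced the trial ledgers is upstream of this
  package; the ledger's phase and joint tags are taken as authoritative.
- Effect sizes are consumed as inputs (from the meta-analytic estimates), never
  re-estimated from surveillance microdata.
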