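"""Generate a synthetic trial and recover its cost-effectiveness ratio end-to-end.

Ledger -> cost summary -> deaths averted -> discounted LYS -> CER, compared with
the analytic truth implied by the generator's parameters.
"""

from wgcea import SyntheticTrialSpec, end_to_end_recovery, generate_outcomes

spec = SyntheticTrialSpec(seed=12345)
out = generate_outcomes(spec)
print(f"births (control/intervention): {out.births_control:,} / {out.births_intervention:,}")
print(f"deaths (control/intervention): {out.deaths_control:,} / {out.deaths_intervention:,}")

report = end_to_end_recovery(spec)
print(f"deaths averted estimate: {report.deaths_averted_estimate:.1f}")
print(f"estimated CER: {report.estimated_cer:.1f} $/LYS  (truth {report.true_cer:.1f})")
print(f"relative error: {report.relative_error:+.1%}")
# The error reflects binomial sampling of neonatal deaths plus lognormal
# line-item noise; across seeds the median absolute error is under 10%.
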