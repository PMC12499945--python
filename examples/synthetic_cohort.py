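"""Generate and analyze a synthetic stepwise-gradient cohort.

Draws 29 cases with clinically plausible prescriptions (outer shell 2-5 Gy,
intermediate 4-9 Gy, inner 6-12 Gy; 1 gradient + 4-27 uniform fractions),
analyzes each against its conventional comparator, and summarizes the
percent EQD2 differences.
"""

import numpy as np

from stepgrad import LQParams, analyze_regimen, make_synthetic_cohort, relative_difference

params = LQParams()
cases = make_synthetic_cohort(29, seed=1)

d_fr, d_total = [], []
for case in cases:
    g = analyze_regimen(case.gradient, params)
    c = analyze_regimen(case.conventional, params)
    d_fr.append(relative_difference(g.first_fraction_eqd2, c.first_fraction_eqd2))
    d_total.append(relative_difference(g.total_eqd2, c.total_eqd2))

d_fr, d_total = np.array(d_fr), np.array(d_total)
print(f"synthetic cohort of {len(cases)} cases")
print(
    f"first-fraction EQD2 excess: mean {d_fr.mean():.0f}% "
    f"(min {d_fr.min():.0f}, max {d_fr.max():.0f}); all positive: {(d_fr > 0).all()}"
)
print(
    f"full-course EQD2 excess:    mean {d_total.mean():.1f}% "
    f"(min {d_total.min():.1f}, max {d_total.max():.1f})"
)
print()
print(
    "Every synthetic case shows a positive first-fraction excess — the\n"
    "gradient fraction's EUD always beats the uniform outer dose — while\n"
    "course totals stay close, mirroring the pattern in the real cohort.\n"
    "Shell volume fractions here are NOT calibrated to any real patient."
)
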