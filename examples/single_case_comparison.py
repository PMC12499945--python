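"""Compare a stepwise-gradient regimen against its conventional comparator.

Builds a three-shell gradient fraction (3/9/12 Gy over 50/30/20% of the
volume) followed by nine uniform 3 Gy fractions, and the conventional
alternative of ten uniform 3 Gy fractions, then reports both on the EQD2
scale with Monte Carlo uncertainties.
"""

from stepgrad import DVH, LQParams, MCConfig
from stepgrad.report import format_report, regimen_mc_report
from stepgrad.regimen import Regimen

gradient_fraction = DVH(
    bin_dose=[3.0, 9.0, 12.0], bin_fraction=[0.5, 0.3, 0.2], label="stepwise"
)
uniform_fraction = DVH(bin_dose=[3.0], bin_fraction=[1.0], label="uniform")

gradient = Regimen(phases=((gradient_fraction, 1), (uniform_fraction, 9)))
conventional = Regimen(phases=((uniform_fraction, 10),))

report = regimen_mc_report(
    gradient, conventional, LQParams(), MCConfig(seed=1)
)
print(format_report(report))
print()
print(
    "The gradient fraction is worth more biological dose than a uniform one\n"
    "(its EUD exceeds 3 Gy because the high-dose shells dominate survival),\n"
    "so the first-fraction EQD2 difference is large, while over the whole\n"
    "course the two regimens stay within a few percent of each other."
)
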