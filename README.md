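# stepgrad

Radiobiological analysis of **stepwise-gradient radiotherapy** — a form of
spatially fractionated radiotherapy (SFRT) for bulky tumors in which the
first fraction deliberately delivers a heterogeneous dose over nested
concentric target volumes (an outer shell near conventional dose, typically
3–4 Gy; an intermediate shell at 6–9 Gy; an inner ablative core at 9–12 Gy),
followed by conventional uniform fractions.

The package answers one quantitative question: *how much more biological
dose does the gradient fraction deliver than the uniform fraction it
replaces, and how different are the complete courses?* It does so on the
common scale of the equivalent uniform dose (EUD) and the equivalent dose
in 2 Gy fractions (EQD2), with Monte Carlo uncertainty propagation, and it
ships a 29-case clinical cohort (as reviewable delimited text) whose every
derived statistic it recomputes.

## Model

Cell survival after a uniform dose *d* follows the linear-quadratic model

    SF(d) = exp(−αd − βd²),   with α = 0.3 Gy⁻¹, β = 0.03 Gy⁻², α/β = 10 Gy.

For a heterogeneous distribution described by a differential DVH with
volume fractions νᵢ at doses dᵢ (uniform cell density assumed), the mean
survival is S̄ = Σ νᵢ·SF(dᵢ), and the **EUD** is the unique uniform dose
with SF(EUD) = S̄ — here solved in closed form from the LQ quadratic.

A fraction of equivalent uniform dose *e* contributes
e·(e + α/β)/(2 + α/β) Gy of **EQD2**, and fractions add. A conventional
course of *n* uniform fractions has EQD2 = n·f(EUD_c); a gradient course
replaces the first term with f(EUD_gradient). The per-case comparison
reports Δ₁fr and Δ_total, the percent EQD2 excess of the gradient regimen
for the first fraction and the full course.

Uncertainty: α and β carry 30% relative standard uncertainties, propagated
by Monte Carlo (10,000 draws by default) and reported as mean ± SD
(coverage factor k = 1).

## Worked example

```python
from stepgrad import DVH, LQParams, MCConfig
from stepgrad.regimen import Regimen
from stepgrad.report import regimen_mc_report, format_report

gradient_fraction = DVH(bin_dose=[3, 9, 12], bin_fraction=[0.5, 0.3, 0.2])
uniform_fraction = DVH(bin_dose=[3.0], bin_fraction=[1.0])

gradient = Regimen(phases=((gradient_fraction, 1), (uniform_fraction, 9)))
conventional = Regimen(phases=((uniform_fraction, 10),))

print(format_report(regimen_mc_report(gradient, conventional,
                                      LQParams(), MCConfig(seed=1))))
```

prints

```
  gradient (test):
    phase 1: 1 fx, EUD 4.359 +/- 0.27, EQD2/fr 5.294 +/- 0.72 Gy
    phase 2: 9 fx, EUD 3 +/- 0, EQD2/fr 3.266 +/- 0.11 Gy
  conventional (reference):
    phase 1: 10 fx, EUD 3 +/- 0, EQD2/fr 3.266 +/- 0.11 Gy

  first fraction EQD2: 5.294 +/- 0.72 vs 3.266 +/- 0.11 Gy
  course total EQD2:   34.68 +/- 1.6 vs 32.66 +/- 1.1 Gy
  delta first fraction: 61.76 +/- 17 %
  delta total course:   6.176 +/- 1.7 %
```

The gradient fraction's EUD (4.36 Gy) exceeds the 3 Gy uniform dose because
the high-dose shells dominate survival, so its single-fraction EQD2 is ~62%
higher; over the whole ten-fraction course the excess shrinks to ~6%.

More narrative walk-throughs live in `examples/` (single-case comparison,
cohort reproduction, uncertainty propagation, synthetic cohort), and a thin
CLI wraps the same calls:

```bash
stepgrad analyze --config run.yaml     # DVH files on disk
stepgrad reproduce-cohort              # the packaged 29-case cohort
stepgrad simulate --n-cases 29 --seed 1
```

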