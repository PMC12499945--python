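# Methods

## The model and its assumptions

The analysis treats dose heterogeneity through its effect on clonogenic
survival. For a structure with differential DVH {(dᵢ, νᵢ)} the mean
surviving fraction under the linear-quadratic (LQ) model is

    S̄ = Σᵢ νᵢ · exp(−α·dᵢ − β·dᵢ²),

which assumes (i) uniform clonogen density, so absolute volume and cell
number cancel and only volume fractions matter; (ii) no repopulation,
reoxygenation or repair kinetics between fractions; (iii) LQ validity at
ablative per-fraction doses up to ~12 Gy, where the model is known to be an
approximation. The equivalent uniform dose is defined by SF(EUD) = S̄ and
computed in closed form as the positive root of α·d + β·d² = −ln S̄:

    EUD = (−α + √(α² + 4β·L)) / (2β),   L = −ln S̄   (EUD = L/α when β = 0).

A bracketing bisection root of the defining equality is kept in the test
suite as an independent oracle; the two agree to 1e−9 Gy on randomized
histograms. Because SF is convex whenever α² ≥ 2β (amply true at the
defaults), Jensen's inequality pins min-dose ≤ EUD ≤ mean-dose, which the
suite asserts as a property.

EQD2 conversion: a fraction of (equivalent uniform) dose e contributes
e·(e + α/β)/(2 + α/β); fractions add. The fraction count *n* of a course
counts **all** fractions including the gradient one — a "1+9" schedule is
n = 10 — which is the only reading under which the packaged cohort's
conventional totals equal n × per-fraction EQD2 (e.g. 10 × 3.25 = 32.5).
Regimens with more than two phases are handled by summing per-fraction
EQD2 over arbitrarily many (DVH, count) phases; no special three-phase
formula exists or is needed.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| α | 0.3 | Gy⁻¹ | standard tumor value used for all cohort calculations |
| β | 0.03 | Gy⁻² | gives α/β = 10 Gy, the conventional tumor ratio |
| cv | 0.30 | — | relative standard uncertainty on α and β |
| n_samples | 10,000 | — | SE of the reported SD ≈ 0.7% of the SD |

α/β is stored as derived from α and β, never as a free third parameter:
the three defaults are mutually consistent and cannot vary independently.

## Monte Carlo uncertainty

Draws are α ~ N(α₀, cv·α₀), β ~ N(β₀, cv·β₀), independent, with rejection
(not clipping) at the physical bounds α > 0, β ≥ 0 to avoid a point mass at
the bound; at cv = 0.30 the rejection probability is ~4e−4 per draw. Every
quantity is re-evaluated per draw and reported as mean ± SD (ddof = 1,
k = 1). Differences between regimens are formed per draw, so shared
parameter uncertainty cancels where it should. An alternative `ratio` mode
samples R = α/β ~ N(R₀, cv·R₀) directly (β = α/R), for sensitivity
analyses in which the 30% is meant to apply to the ratio itself; the
independent mode is the default.

A caveat the package states deliberately: at cv = 0.30 the sampled ratio
α/β is strongly right-skewed (small-β draws), and first-order (delta
method) error propagation understates the Monte Carlo SD of per-fraction
EQD2 by roughly 20–30% (e.g. 0.107 vs 0.088 Gy for a uniform 3 Gy
fraction). The agreement is within 2% at cv ≤ 0.05 and within 10% at
cv = 0.10, which the suite asserts. All quoted uncertainties therefore come
from the Monte Carlo, never from linear propagation.

For uniform (single-bin) phases the EUD equals the prescription dose
identically, independent of the parameters; the implementation returns it
exactly, so all uncertainty of such phases enters through the EQD2
conversion — an exactly assertable invariant.

## Cohort recomputation and rounding

The packaged 29-case tables store values **as printed**, to their original
decimal precision, in reviewable TSV. Every derived quantity — per-case
Δ₁fr = 100·(EQD2_gradient,fr − EQD2_c,fr)/EQD2_c,fr, Δ_total, cohort
mean/min/max, response rates, medians — is recomputed from the primary
columns.

Recomputed ratios cannot be expected to match printed ones to the last
digit, because the source computed them from unrounded values: a printed
pair (5.0, 2.35) constrains the true ratio only to the interval spanned by
(4.95…5.05)/(2.345…2.355). Consistency is therefore checked by interval
arithmetic: each printed value x with k decimals stands for x ± 0.5·10⁻ᵏ,
and the printed Δ (widened by half its own ULP) must overlap the interval
of ratios its inputs allow. The same propagation gives the per-row
tolerance for the EQD2 additivity identities

    total_gradient = fr_gradient + k·fr_c,    total_c = (k+1)·fr_c,

namely half a ULP of each printed figure carried through the arithmetic
(for a count-19 schedule with two-decimal per-fraction values this is
~0.15 Gy; for count-4 schedules with one-decimal values, up to 0.3 Gy).
Cases with a third treatment phase are exempt from the two-phase gradient
identity only. Cohort summary comparisons use the mean of the per-case
interval half-widths as their tolerance.

Medians over an even count use the midpoint of the two central values;
non-assessable cases are excluded from the volume-reduction median (26
assessable of 29) but retained in response-rate denominators (29), matching
how each statistic is defined.

## Synthetic plans

The synthetic generator emulates the *prescription structure* of stepwise
gradient plans, not any individual patient. Defaults: three shells at
3/9/12 Gy with volume fractions 0.5/0.3/0.2 (chosen to place synthetic
EUDs inside the clinically observed per-fraction EQD2 range of roughly
2.6–8.7 Gy), boundary-gradient smearing of 0.5 Gy and intra-shell noise of
0.2 Gy (combined in quadrature), 20,000 sampled voxels, 0.05 Gy bins.
Cohort-scale generation draws schedules of 1 gradient + 4–27 uniform
fractions, outer doses 2–5 Gy in quarter-Gy steps, intermediate and inner
doses escalating into the 4–9 and 6–12 Gy bands, and Dirichlet-scattered
shell fractions around the default.

With zero smearing and noise the DVH degenerates to exactly one bin per
distinct shell dose. A second, geometric generator voxelizes concentric
spheres on a cubic grid (default 0.3 cm spacing, matching typical dose-grid
resolution) and histograms the piecewise-constant radial dose; its shell
fractions converge to the analytic sphere-shell volume ratios as the grid
refines, which the suite checks at 0.1 cm against (19/27, 7/27, 1/27).

What the synthetic data does **not** emulate: deliverable beam arrangements
and their penumbra shapes, organ-at-risk constraints pushing dose off the
target, inter-fraction anatomy change, or per-patient shell volume
fractions (unpublished). Passing tests on synthetic plans therefore
validate the analysis pipeline, not the dosimetric realism of any plan.
Absolute per-case gradient EQD2 values of the real cohort require the
patients' actual DVHs, which are not published; for those cases the package
verifies inter-column consistency instead.

## Numerical choices

- Mean survival is accumulated via log-sum-exp, so high-dose bins whose
  survival underflows in linear space still contribute correctly.
- Cumulative→differential conversion uses interval midpoints as bin
  representative doses (unbiased for piecewise-uniform dose in a bin);
  residual volume at the top dose point becomes a terminal bin.
- DVH fractions summing to 1 within 1e−3 are renormalized with a logged
  warning; worse totals are rejected as malformed.
- Sample SDs use ddof = 1; a degenerate (constant) sample reports exactly 0
  rather than float-epsilon noise.
- All randomness flows through `numpy.random.default_rng` seeds; cohort
  generation derives per-case substreams from the master seed, and equal
  seeds give byte-identical outputs.

## Known limitations

The EUD/EQD2 comparison is an approximate effect estimate: it ignores the
immunological and bystander mechanisms hypothesized to drive SFRT response,
treats α and β as spatially uniform, and inherits LQ's questionable
accuracy above ~10 Gy per fraction. The cohort tables are transcribed
fixtures — clinical endpoints in them are data, not computed outputs.
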