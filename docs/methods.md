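# Methods

## Design and coding

A central composite design for k factors holds 2ᵏ factorial corners (coded
±1), 2k axial points at distance α along each axis, and n_c replicated
center points. `build_ccd` defaults to the rotatable α = (2ᵏ)^¼ (√2 for
k = 2); face-centered (α = 1) and explicit α are available. The coded map is
affine per factor, actual = center + half_range · coded, and is exact to
machine precision in both directions. Run order is deterministic
(factorial corners in lexicographic coded order, axial pairs, centers);
a seedable shuffle exists but is off by default because the source study
reports no randomization.

The packaged 13-run study table stores the coded levels as ground truth and
derives the actual columns from them; one printed actual level (run F5's
PC:VA "1.050") is a typo for the center level 2.050 and is corrected that
way. For k = 2 with α = √2 the coded columns satisfy Σxᵢ = 0, Σxᵢ² = 8 and
Σ(x₁x₂)² = 4, which the diagnostics rely on.

Zeta potential is stored signed (negative mV) as measured, but modelled as
a magnitude: the fitted |ZP| intercept equals the center-point |ZP| mean,
confirming that convention, and "maximize ZP" scientifically means "larger
magnitude = more colloidal stability". Reports re-attach the sign.

## Quadratic fit and ANOVA

The full 6-term (for k = 2) second-order polynomial is always fitted in
coded units by SVD least squares; no term selection, because the per-term
ANOVA tests each term inside the full model. Coded units are not cosmetic:
the partial sums of squares only reproduce the published table in coded
units. Partial (type III) SS are computed as bⱼ²/[(XᵀX)⁻¹]ⱼⱼ, which equals
the drop-one extra SS for every term and reduces to bᵢ²Σxᵢ² / b₁₂²Σ(x₁x₂)²
for the orthogonal columns. Replicate-SD columns are carried through I/O
but ignored by the fit (the model describes run means).

Pure error is the within-replicate-group scatter (runs sharing identical
coded levels); lack of fit is the remaining residual SS, F-tested against
the pure-error mean square. Degrees of freedom are derived from counts
(model p−1 = 5, residual n−p = 7, LOF 3, pure error 4 for the 13-run
design), never hard-coded. PRESS uses the OLS leverage identity
e₍ᵣ₎ = eᵣ/(1−hᵣ) and is verified in tests against literal leave-one-out
refits. "Adequate precision" follows the DoE-software convention
(range of fitted values over √(p·MS_res/n)); that choice reproduces the
published 30.183/16.164/25.747 from the design-table refit. p-values below
1e-4 print as "< 0.0001" but are stored at full precision.

Numerical notes: rank deficiency is detected at σ_min ≤ 1e-10 σ_max and
reported with the collinear column names taken from the null singular
vector; a leverage of 1 makes PRESS undefined and raises rather than
returning infinity.

## Desirability optimization

Individual desirabilities are the standard one-sided ramps
(minimize: d = clip((upper−y)/(upper−lower))ʷ; maximize mirrored; target:
two-sided ramp), combined as D = (∏ dᵢ^rᵢ)^(1/Σrᵢ). Ramp bounds default to
each response's observed min/max over the design and weights/importances
default to 1 — the defaults of standard DoE software, and the source study
states no others. The search region defaults to the coded factorial box
[−1, 1]²; an axial disc ‖x‖ ≤ α is available.

The optimizer is deterministic: a dense grid scan (default step 0.01),
detection of all grid-local maxima, bounded Nelder–Mead refinement from
each, and deduplication. All distinct local optima are returned (best
first) alongside the selected optimum, emulating the multi-solution list of
commercial packages. This matters here: the study's desirability program is
bimodal. The refit models give a global box maximum D ≈ 0.757 at coded
(+1, ≈0.01) (PC:VA 2.8:1), while the published optimum — coded (−1, +0.127),
i.e. 1.3:1 at 53.16 mg/mL, predicted PS 278.93, D ≈ 0.52 — is the *other*
local solution's basin, which the enumeration recovers. The package reports
both rather than silently choosing; selecting the lower-D basin is a
formulation judgement (e.g. lipid economy), not a property of the
mathematics. The published PS %bias (21.43%) is also inconsistent with the
bias formula applied to its own expected/observed pair (17.65%); the
package always reports the formula value.

## Physicochemical and bioanalytical calculators

P = C_octanol/C_water and Log P = log₁₀P. Detection limits use the ICH
σ/S rules with factors 3.3 and 10, σ being the residual SD of the
calibration line (√(SS_res/(n−2))) — this reproduces the published
LOD 0.317 / LOQ 0.961 µg/mL exactly from the printed σ and slope.
Extraction recovery (pre/post-extracted × 100) and matrix effect
(post-extracted/post-neat) are simple guarded ratios. Chromatographic
system-suitability numbers are user-entered and echoed; no peak
integration is attempted (no raw chromatograms exist).

## Non-compartmental PK

Linear trapezoids throughout (the convention the study states), with a
(0, 0) anchor for oral dosing when the first sample is post-dose. λz comes
from log-linear OLS on the last 3 samples by default (configurable); a
non-positive or non-declining tail suppresses extrapolation with a warning
instead of guessing. Tmax ties break to the earliest time. All times are
minutes. Relative bioavailability is the percent ratio of dose-normalized
AUC∞. Group summaries are mean ± SEM over subject-level NCA results.

## Synthetic data

CCD responses: y = Xβ_true + N(0, σ); Gaussian because the responses are
means of replicate instrument reads. PK: the one-compartment oral model
with mean-preserving lognormal between-subject variability on the
concentration scale and lognormal residual noise per sample (keeps
concentrations positive). The generator returns the analytic truths
(AUC∞ = D/(V/F·ke), MRT = 1/ka + 1/ke, Tmax = ln(ka/ke)/(ka−ke)) for
testing. Each stage consumes one numpy Generator; the pipeline splits a
single top-level seed with `SeedSequence.spawn`.

The PK presets emulate the two study groups at 10 mg/kg oral dosing,
chosen once to match each group's reported Tmax, MRT and AUC∞:
standard drug ka = 0.59 min⁻¹, ke = 1.75e-3 min⁻¹, V/F = 0.0788 L/kg
(Tmax ≈ 9.9 min, MRT ≈ 573 min); formulation ka = 0.20 min⁻¹,
ke = 5.734e-4 min⁻¹, V/F = 0.0626 L/kg (Tmax ≈ 29.4 min, MRT ≈ 1749 min).
Between-subject and residual CVs default to 15% and 10%, typical for small
rodent PK studies.

What the generator does *not* emulate: enterohepatic recirculation or any
multi-compartment disposition, below-LOQ censoring, sampling-time jitter,
and correlated assay error — so passing tests demonstrate correctness of
the estimators under the stated model, not robustness to those features of
real data.

### Trapezoidal bias at the study schedule

The linear trapezoid overestimates a convex decaying curve. At the study's
sparse 9-point schedule (10–2880 min) the implied AUC∞ bias is an intrinsic
property of (parameters, schedule): ≈ +16.2% for the standard-drug preset
(dominated by the 360→1440→2880 min chords) and ≈ +2.5% for the
formulation preset; at dense sampling it falls below 1%. Tests assert that
the NCA error *equals* this closed-form bias rather than some looser cap,
and the group-ratio consequences (e.g. relative bioavailability computed
from sparse noise-free profiles lands near 339%, not the analytic 384%)
follow from the same arithmetic.

## Known limitations

- Desirability search grids scale as (2/step)ᵏ; for k > 3 the scan step is
  coarsened automatically and the refinement does the fine work.
- The ANOVA assumes the replicate groups exhaust the pure-error
  information; designs without replicates drop the lack-of-fit partition.
- No weighted least squares, response transformations, or mixture designs.
- NCA offers no lin-up/log-down trapezoid and no AUC truncation at a fixed
  horizon; the published 0–24 h column is not reproduced (it is internally
  inconsistent in the source) and is out of scope.
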