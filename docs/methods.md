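# Methods

## The problem

Percent body fat (%BF) can be estimated cheaply from skinfold calipers or
bioelectrical impedance (BIA), or accurately from dual-energy X-ray
absorptiometry (DXA). Whether the cheap methods can substitute for DXA is a
question of *agreement*, not correlation: two methods can correlate strongly
while one reads systematically high. This package implements the standard
method-comparison toolkit for that question, applied to adult women of
reproductive age, together with an observer-reliability analysis of the
skinfold measurements themselves.

## Prediction chain

Skinfold thicknesses (mm, caliper, triplicate means per site) feed one of
two sex-specific body-density equations:

* three-site (triceps + suprailiac + medial thigh = S₃):
  `D = 1.0994921 − 0.0009929 S₃ + 0.0000023 S₃² − 0.0001392 age`.
  The quadratic's vertex is at S₃ ≈ 215.85 mm, so the equation is strictly
  decreasing over the measurable range (we assert this on a grid).
* four-site (average axillary + suprailiac + medial thigh + medial calf =
  S₄): `D = 1.1954713 − 0.07513507 log₁₀ S₄ − 0.00041072 age`.

Density converts to %BF through the two-compartment Siri equation
`%BF = 495/D − 450` (zero fat at exactly D = 1.1). All arithmetic is carried
in double precision; rounding is a presentation concern. Negative %BF from
very lean inputs is returned as computed and flagged, never clipped —
clipping would bias the downstream agreement statistics. Age is a real in
years. The subscapular site is carried in the data model for completeness of
the measurement record although neither equation uses it.

## Agreement statistics

**Lin's CCC.** ρ̂_c = 2 s_xy / (s_x² + s_y² + (x̄ − ȳ)²) with *n*-denominator
moments (the original derivation's convention; descriptive SDs elsewhere use
n−1). It factors as ρ̂_c = r · C_b with C_b = 2 s_x s_y / (s_x² + s_y² +
(x̄ − ȳ)²) ∈ (0, 1], so |ρ̂_c| ≤ |r| always. The CI transforms Ẑ = atanh(ρ̂_c)
with asymptotic variance

    σ²_Ẑ = (1/(n−2)) [ (1−r²)ρ̂_c²/((1−ρ̂_c²)r²)
                       + 4ρ̂_c³(1−ρ̂_c)u²/(r(1−ρ̂_c²)²)
                       − 2ρ̂_c⁴u⁴/(r²(1−ρ̂_c²)²) ],   u = (x̄−ȳ)/√(s_x s_y),

the corrected form of Lin's variance; the code rewrites each term through
C_b = ρ̂_c/r so that r = 0 is not a singularity. Empirical coverage of the
95% interval is checked by simulation (1,000 bivariate-normal replicates at
n = 90; observed coverage must fall in [93%, 97%]). |ρ̂_c| = 1 degenerates to
a point interval with a warning.

**St. Laurent's gold-standard coefficient.** With deviations D_i = test_i −
gold_i: r̂_G = S_GG / (S_GG + S_DD), S_GG the centred gold sum of squares and
S_DD = ΣD_i² *uncentred* — systematic bias counts against agreement. The
estimator is a variance ratio and lies in [0, 1] (attaining 1 only on exact
agreement); descriptions of the coefficient as ranging over [−1, 1] refer to
a different estimator form, and we document ours as nonnegative. Under the
model test = gold + bias δ + noise(σ_D), the population value is
σ_G²/(σ_G² + σ_D² + δ²), which the sample coefficient recovers within ±0.02
at n = 5,000 in tests. The CI is a seeded percentile bootstrap (default
B = 2,000, resampling pairs); resamples with constant gold are skipped, and
the interval is clamped to bracket the point estimate. An F-based exact
interval could be added behind the same interface.

**Bland-Altman.** Bias = mean(x−y), limits of agreement bias ± m·SD(diff),
default m = 1.96 with a `reproduction_mode` switch to m = 2 (the convention
of the figures being emulated). The bias CI is the exact t interval; the LoA
CIs use the approximate SE = SD·√(1/n + m²/(2(n−1))). The per-pair (average,
difference) table is returned for plotting; the package emits plot *data*,
not figures.

**Paired comparison.** Two-sided paired t-test by default, Wilcoxon
signed-rank behind a config switch. At the pipeline level a zero-variance
difference (identical methods) yields a NaN-statistic row rather than a
crash, since the degenerate case is legitimate for synthetic zero-noise
cohorts.

**ICC sample-size planning.** Bonett's precision approximation
n = ⌈1 + 8z²(1−ρ)²[1+(k−1)ρ]²/(k(k−1)w²)⌉ for a (1−α) CI of width w with k
raters. At ρ = 0.70, w = 0.20, k = 2 this gives 101 (the ceiling makes the
answer conservative; reports of 100 for this planning point round the
real-valued solution down). Only the planning formula is provided; the ICC
itself is not estimated from data.

## Pipeline layout

The inter-method report covers exactly seven method pairs: Lin's CCC for the
four pairs not involving the reference method (%BF JPW–PET, ΣSF JPW–PET,
%BF JPW–BIA, %BF PET–BIA) and the St. Laurent coefficient for the three
DXA-referenced pairs (JPW, PET, BIA vs DXA), with Bland-Altman summaries for
all seven. DXA is always the gold argument, and differences are reported as
method − DXA so that under-reading appears with a negative sign. Changing
the pair set requires code, never happens silently. Input CSVs are validated
row by row; excluded rows are logged with row numbers, and analysis n plus
exclusions always equals the input row count.

## Synthetic cohorts

The generators stand in for undeposited subject-level data; their defaults
*are* the study conditions and are not tuned per run.

* **Inter-method cohort (n = 90).** Ages and body size from truncated
  normals at the published means/SDs/ranges; the six skinfold sites from a
  truncated multivariate normal (published means/SDs, exchangeable
  correlation 0.6 — the publication prints no correlation structure, so this
  is a config default, not a claim) with every site constrained to
  (2, 100) mm by rejection sampling (capped iterations). %BF by the two
  skinfold equations is computed exactly through the prediction chain. DXA
  and BIA are generated as latent-plus-offset-plus-noise with the subject's
  three-site %BF as the latent reference: DXA = latent + 5.4 + N(0, 4.5²),
  BIA = latent + 0 + N(0, 4.7²). The +5.4 offset is the published mean gap
  between DXA and the three-site estimate; the noise SDs sit near the
  published paired-difference SDs. This reproduces the published ordering
  (DXA highest; the four-site equation lowest) without inventing joint
  structure the summary tables do not constrain.
* **Reliability sample (n = 59).** True site values per subject, then three
  passes: observer A's passes add only iid reading noise (default SD 0.1 mm
  per reading, matching near-unity intra-observer concordance); observer B
  adds a site-specific systematic bias (−0.45 / +3.68 / +0.19 mm for
  triceps / suprailiac / medial thigh — the published between-observer mean
  gaps, largest at the suprailiac) plus a per-subject random disagreement
  (SD 0.9 / 3.8 / 4.7 mm, back-solved from the published inter-observer
  concordance levels; bias alone cannot reproduce the observed ordering in
  which the medial thigh, despite near-zero mean bias, agrees worse than the
  triceps). Readings are floored at 0.2 mm (caliper resolution).

Known generator limitations, hence what passing tests do and do not show:
the truncation floor shifts site means up by ~0.4–0.6 mm (accept rate
≈ 0.96), so sample moments converge to the configured ones only up to that
documented shift; age is drawn independently of adiposity; DXA/BIA share no
error correlation with the skinfold methods beyond the common latent; there
is no BMI-subgroup structure. Passing the directional acceptance checks
shows the statistics behave correctly under the published summary structure,
not that real DXA/BIA data would yield the same coefficients. The
subscapular site's generator parameters (mean 20, SD 8 mm) are placeholders:
no published summary constrains them and no equation consumes the site.

One internal inconsistency of the published summaries is worth recording:
evaluating the printed four-site equation at the printed mean ΣSF (100.06 mm)
and mean age gives D ≈ 1.033 and %BF ≈ 29, while the printed summary lists
density 1.05 and %BF 22.5 for that method. The generator computes through
the printed equation, so its four-site %BF mean is ≈ 29; the qualitative
ordering of the methods is unaffected.

## Numerical and design choices

Seeds: every stochastic component (cohort draws, observer noise, bootstrap)
takes an explicit seed; same seed ⇒ byte-identical outputs, and the run
manifest records seed, options and complete-case counts. Medians of
even-length vectors average the central order statistics. Missing data are
handled by complete-case (pairwise) deletion with logged counts — no
imputation. Intra-method comparisons use observer A's first pass
(configurable). Qualitative CCC labels ("satisfactory", "moderate") are
annotation only and never enter any computation. Problem sizes in tests
(1,000 oracle samples, 1,000 CI replicates at n = 90, n = 5,000 recovery,
n = 20,000 moment checks) keep the full suite in a few seconds while leaving
Monte-Carlo error well inside the asserted tolerances.
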