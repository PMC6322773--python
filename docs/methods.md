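# Methods

## The virtual-study model

A virtual weight-estimation study applies a system's lookup rules to a
database of measured anthropometry and scores the resulting estimates
against measured weight. The unit of analysis is the signed percentage
error PE = 100·(estimated − actual)/actual; percentage error is preferred
over kg error because measured weights in under-five cohorts span nearly an
order of magnitude, so a fixed kg error has very different clinical meaning
across the range.

Per method and (sub)population the package reports:

* **Bias**: MPE = mean(PE).
* **Precision**: Bland–Altman 95% limits of agreement MPE ± 1.96·SD(PE)
  (SD with the n−1 denominator, the Bland–Altman convention), and
  RMSPE = √(mean(PE²)). Report tables conventionally print a second,
  parenthetical spread figure beside RMSPE; this package reports the SD of
  |PE| there (`rmspe_companion`) and labels it as an interpretation, since
  the convention is not standardised.
* **Overall accuracy**: p10 and p20, the percentage of estimates with
  |PE| ≤ 10 and ≤ 20. Acceptability is p10 ≥ 70% **and** p20 ≥ 95%
  (inclusive; both thresholds configurable), the bar conventional in this
  literature.

## Imputation of p10/p20 from published summaries

When a method's published record contains only (MPE, LOA), p10/p20 are
imputed under normality: σ is recovered from the LOA width,
σ = (loa_high − loa_low)/(2·1.96) — robust to one-sided rounding of the
printed limits — and

p_t = 100·[Φ((t − μ)/σ) − Φ((−t − μ)/σ)],  t ∈ {10, 20},

i.e. the integral of the error distribution N(μ, σ) over [−t, +t]. This is
the only reading of the usual printed formula (which nominally integrates
around "mean actual weight") that reproduces published imputed cells, and
it is exact when PE is normal. The package verifies it against both
quadrature and Monte-Carlo simulation.

## Paired comparisons

Two methods evaluated on the same children are compared pairwise:

* **p10/p20**: McNemar's test on the discordant counts b (A accurate only)
  and c (B accurate only) — exact two-sided binomial(b, b+c, ½) when
  b + c < 25, continuity-corrected χ² = (|b − c| − 1)²/(b + c) with 1 df
  otherwise (switch point configurable). Effect size is the matched-pairs
  odds ratio b/c with a log-scale Wald 95% CI; a zero cell gets the ½
  continuity correction and is flagged.
* **MPE**: paired t-test on the matched PE lists. A paired test "of RMSPE"
  is not well defined (RMSPE is a scalar per method); where such a contrast
  is wanted the paired t on |PE| is the nearest defensible analogue.
* Policy defaults: significance at p < 0.001 (appropriate to very large n
  and multiple testing) and clinical importance at an absolute difference
  greater than 10 points in the compared parameter; both configurable.
* Degenerate tables (no discordant pairs — e.g. a method compared with
  itself) are reported as null comparisons (p = 1, OR = 1, flagged), not
  errors. Records are excluded pairwise: only from comparisons involving a
  method that could not estimate them.

## Tape estimators

All tapes share the segment conventions: half-open length segments
[lower, upper) in cm, validated at load time to be contiguous and
non-overlapping with non-decreasing weights; a length outside the tape is
an out-of-range *result*, counted and excluded from summaries, never an
exception. MAC is stored in cm with mm accepted at the interface.

* PAWPER XL-MAC: within the located segment, the habitus index is the
  number of MAC cut-offs ≤ MAC (a MAC exactly at a cut-off belongs to the
  higher habitus category — stated once here, tested everywhere); the
  segment row carries one weight per habitus category (up to seven).
* Broselow: one weight per segment; the 2007B and 2011A editions are
  independent calibrations distinguished in the method identifier.
* Ralston: the MAC band is severe < 115 mm, moderate 115–125 mm inclusive
  on both edges, normal > 125 mm; each band has its own length tape.

## Growth reference (LMS)

z = ((X/M)^L − 1)/(L·S), with the log form ln(X/M)/S when |L| < 1e−12, and
the exact inverse X = M·(1 + L·S·z)^(1/L). For weight-based indicators
(weight-for-age, weight-for-height, BMI-for-age) the WHO-style restricted
adjustment replaces z beyond ±3 with a linear scale in units of the gap
between the 2-SD and 3-SD curves (z' = 3 + (X − SD3)/(SD3 − SD2), mirrored
below −3); it is on by default for those indicators and switchable off.
Tables are (axis, L, M, S) grids per indicator and sex — axis in completed
months for age-based indicators, length/height in cm for weight-for-height
— linearly interpolated, with out-of-grid queries raising an error that
carries the valid interval. Classification bins: the five-level BMI-for-age
habitus scheme (underweight Z ≤ −2.0; thin −2.0 < Z ≤ −1.4; normal
−1.4 < Z < 1.4; overweight 1.4 ≤ Z < 2.0; obese Z ≥ 2.0) and the
three-level deficit schemes (normal Z ≥ −2.0; moderate −3.0 ≤ Z < −2.0;
severe Z < −3.0). Published three-level tables sometimes print the middle
bin with inverted inequality signs; the implementation follows the
prose definition (moderate = [−3, −2)).

## Subgroup pipeline

Default strata: sex; age in completed months {6–12, 13–24, 25–36, 37–48,
>48}; weight {≤10 kg, (10, 15] kg, >15 kg} (10.0 kg falls in the lower bin,
matching the printed "≤10 / 10.1–15" labels); BMI-for-age five bins;
weight-for-height three bins; region (country → region via a shipped
editable lookup, unknown countries stratified as "unassigned" rather than
erroring). Pre-computed survey z-scores on the input are used as-is by
default (pass-through), since distributed survey compilations carry their
own z-scores; recomputation against a supplied reference is a switch.
Empty cells are carried with n = 0 and no statistics. Cell membership plus
per-method exclusions conserves the record count, and summaries are
invariant to record order.

## Synthetic cohort generator

The generator emulates the **marginal** structure of pooled under-five
nutritional surveys; defaults (all configurable):

* sex: P(male) = 0.506; age: uniform over completed months 6–59 (pooled
  medians ≈ 30 months sit near the uniform midpoint; an IQR-matched
  distribution can be configured instead);
* HAZ ~ N(−1.5, 1.5) inverted through the height-for-age reference to
  length; WHZ ~ N(−0.6, 1.2) inverted through weight-for-height at that
  length to weight;
* MAC (cm) = 14.655 + 0.02·(age − 32.5) + 0.758·WHZ + ε, ε ~ N(0, 0.876),
  calibrated so the marginal is mean 14.2 cm, SD 1.3 cm with
  corr(MAC, WHZ) ≈ 0.7. The MAC–WHZ dependence in real surveys is unknown;
  the slope is a modelling choice, not an estimate.
* measurement rounding 0.1 cm (length), 0.1 kg (weight), 0.1 cm (MAC) —
  survey convention; latent pre-rounding values are retained so recovery
  tests can separate estimator error from rounding.

HAZ and WHZ are drawn independently given age (surveys publish only
marginals, so no joint copula is identifiable); children whose drawn HAZ
implies a length outside the weight-for-height grid are redrawn with a
capped, logged retry. Generation is byte-identical given (config, seed).

What the generator does **not** emulate: survey design effects and
clustering, seasonality, secular trends over the collection period,
country-level heterogeneity beyond the region mix, and any real joint
HAZ–WHZ dependence. Passing tests on synthetic cohorts therefore validate
the *machinery* (lookup rules, statistics, stratification), not the
clinical performance of any tape on real children.

## Fixtures

The shipped LMS grids are smooth anchor curves with WHO-like medians and
conventional L/S values; the shipped calibrations are derived from them
(per-segment median weight-for-length; PAWPER habitus weights at
weight-for-height z offsets {−3.5, −2.5, −1.5, 0, 1.5, 2.5, 3.5}; MAC
cut-offs from the fixture MAC model at z {−3, −2, −1, 1, 2, 3}; Broselow
2011A offset +0.5 z; Ralston bands at z {−2.5, −1.5, 0}). All are flagged
non-clinical. Full-scale published accuracy figures are not reproducible
from these fixtures — they require the external survey dataset and the
clinical calibration tables, supported as optional inputs only.

## Numerical choices and problem sizes

Exact McNemar p-values use the two-sided doubled-tail convention capped at
1. Segment contiguity is validated to 1e−9 cm. The LMS round-trip property
is held to 1e−9. Simulation-based checks in the test suite use cohorts of
5·10³–10⁶ children and Monte-Carlo samples of 10⁶ draws, sized so that the
assertion tolerances sit at ≥ 4 Monte-Carlo standard errors under fixed
seeds; the full suite runs in well under a minute on one core.

## Known limitations

* The matched-pairs odds ratio b/c is one of several constructions used in
  this literature; published effect sizes may use another.
* The imputation is exact only under normal PE; heavy-tailed or skewed
  error distributions bias it, which is why imputed cells should be marked
  as such in reports.
* Fixture tapes quantise length at 5 cm segments, coarser than real tapes;
  their absolute accuracy numbers are not meaningful, only the machinery
  and orderings they exercise.
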