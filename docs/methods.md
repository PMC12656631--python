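# Methods

## Course difficulty

Difficulty factors extend the ITRA points formula (distance in km plus
gain in m divided by 100) with a downhill analogue so that descent-heavy
sections are weighted too. Each section is classified by its *net*
slope sign — an explicit config field, never re-derived from gain/loss,
so a course file can pin the official classification — and its relative
difficulty coefficient (IRDC) divides the section factor by the
race-level factor of the same sign. IRDC is scale-invariant (scaling
every distance and slope by *k* leaves it unchanged) and lies in
(0, 1].

Two precision modes exist because the published checkpoint equations
embed 2-decimal coefficients (0.27, 0.16, 0.14, 0.08): `rounding="full"`
(the default for fresh analysis) computes IRDC at full floating
precision; `rounding="published"` rounds to two decimals for replication.

The built-in course fixtures carry `idf_override` values on three
sections (and on the 8K race-level downhill factor) where the published
per-section factors differ from recomputation out of the published raw
distance/slope inputs (e.g. section 1: 5.5 km + 1430 m gives 19.8, the
published factor is 20.5; the 8K downhill total gives 147.5, published
148 — presumably upstream rounding or input adjustment). The published
factors are treated as authoritative so every coefficient cell
reproduces exactly; `section_difficulty(..., use_override=False)`
exposes the raw recomputation.

## Features

All time arithmetic is in decimal hours; the CSV reader accepts
HH:MM:SS and decimal-hour cells. Section times are successive
differences of checkpoint passage times (the start is cp0 = 0); a
missing checkpoint voids only the two adjacent sections, and every
downstream feature is missing only when a constituent is missing —
rows are excluded pairwise per analysis, never listwise.

Checkpoint percentile rank is `rank(ascending passage time)/n` over the
field *pooled across modalities* (both modalities share the first five
sections), so the fastest runner has CPR = 1/n and the slowest 1.0;
this orientation makes the positive rank coefficient in the ascent
models interpretable (being further back predicts a later finish).
Ties share the mean rank. Performance quartiles are defined on the
cp1 rank with an inclusive boundary at rank ⌈0.25·n⌉, so a field of
947 puts 237 runners in Q1. The quartile label in the feature table is
taken from cp1, the field's earliest common performance marker.

Weighted-time variability pairs are fixed at (s1, s3), (s2, s4),
(s3, s5): successive sections of the same slope sign, skipping the
opposite-slope section in between.

## Group statistics

Finish-time and weighted-time distributions in race fields are skewed,
so p-values come from a bootstrap: the null is imposed by mean-centering
(each group separately for independent comparisons; the differences for
paired ones), the t statistic is recomputed over 1000 simple random
resamples by default, and the two-sided p is the +1-corrected
exceedance fraction. With Gaussian data this converges to the analytic
t-test p (checked at 0.02 tolerance in the suite), and under the null
its type-I error at α = 0.05 stays within [0.03, 0.07] over 2000
simulated datasets. Independent comparisons use Welch's t by default
because the natural groupings (76 vs 871 by sex) are extremely
unbalanced; a pooled-variance variant is available.

Cohen's d is mean(diff)/SD(diff) for paired comparisons — so slowing
between sections (later WT larger) yields negative d — and
pooled-SD for independent ones; magnitude bands are trivial < 0.2 ≤
small < 0.5 ≤ medium < 0.8 ≤ large. Post hoc power uses the
noncentral-t distribution (Fisher-z for correlations) and equals α at
zero effect by construction. Normality screening reports both a
Lilliefors-corrected Kolmogorov–Smirnov test and Shapiro–Wilk; a
constant sample is reported non-normal with a warning rather than an
error. Every stochastic routine requires an explicit seed.

## Regression and diagnostics

Each terrain segment's model is OLS of TT on the segment's predictor
triple with all three predictors forced in ("enter" method) — no
stepwise selection, so all predictors always appear regardless of
p-value. CPR enters as a fraction in (0, 1], not a percentage; the
standardized betas depend on this choice. Confidence intervals are
analytic t-based.

Influence screening is a single pass: cases with Cook's distance > 1
or |internally studentized residual| > 3 are flagged, removed, and the
model is refitted once (no iteration). Diagnostics reported: adjusted
R² and SEE (which satisfy their defining identities exactly),
Durbin–Watson (acceptable band 1–3), VIF per predictor (concern
threshold 10; perfect collinearity reported as infinite rather than
raised), and Bland–Altman agreement of predicted vs actual times (bias,
±1.96 SD limits, fraction outside, residual normality; a zero-variance
difference is flagged degenerate). The OLS solution, betas, VIF and
Cook's distances are verified in the test suite against brute-force
normal-equation, auxiliary-regression and leave-one-out oracles at
1e-10.

## Prediction

`predict_tt` evaluates a segment model from raw inputs (two section
times, current rank, field size); `expand_closed_form` substitutes the
weighted-time definitions symbolically to produce an evaluable
expression in stopwatch times, and the two paths agree to 1e-10 by
construction (property-tested on random inputs). Only ascent-type
segments expand (their WTV is a ratio of two uphill weighted times).
Replication mode pairs the published ascent-#1 coefficients with
2-decimal course coefficients — reproducing the published 4K/8K
checkpoint equations term-for-term — while research mode pairs a
freshly fitted model with full-precision coefficients; the CLI refuses
mixed requests. The rank supplied at prediction time is the live-timing
rank against whatever field definition the feed uses; mid-race the
final finisher count is unknown, a deliberate divergence from
post-hoc analysis where CPR uses the finisher field.

## Synthetic field generator

The generator encodes the pipeline's own central premise: a latent
per-runner ability *A* on the weighted-time scale, with section times
difficulty-proportional, `T_n = IRDC_n · A · f_n · (1 + ε_n)`. `f_n`
is a per-slope-sign fatigue drift indexed by the section's occurrence
order within its sign; `ε_n` is multiplicative Gaussian noise (clipped
to keep times positive); the course beyond the last shared checkpoint
enters as a single ability-proportional lump, since no section
structure is available for it. In the noiseless, driftless limit every
WT_n equals *A* exactly and every WTV is zero.

Default calibration (chosen once, against the published cohort summary
statistics, and fixed):

| parameter | default | emulates |
|---|---|---|
| field sizes | 764 / 183 | modality split of the 947-runner cohort |
| male fraction | 871/947 | cohort sex ratio |
| ability mean (h) | 7.3 / 16.85 | mean first-ascent weighted time per modality |
| ability CV | 0.14 / 0.16 | weighted-time spread within modality |
| ascent drift | (1, 1.3, 1.3) | ~30% slowing uphill #1→#2, none #2→#3 |
| descent drift | (1, 1.15) | ~15% slowing between descents |
| section noise SD | 0.08 | strong but not deterministic WT correlations |
| remainder factor | 0.374 / 0.576 | total-time means of ≈10 h and ≈18.4 h |

What the generator reproduces: difficulty-proportional pacing with a
strong shared ability signal (corr(WT_n, TT) > 0.9, exceeding
corr(T_n, TT), because raw section times compress modality differences
that weighted times preserve), early-race slowing with a large negative
paired effect size that vanishes by the second ascent, and realistic
quartile structure. What it does not: heavy right-tail skew from
blow-ups and hiking, weather and surface effects, within-runner
terrain-specific skill (uphill vs downhill specialists), DNFs, or
inter-edition course variation. Passing tests on this field therefore
demonstrate pipeline correctness and recoverability under the model's
own assumptions, not agreement with any real cohort — the original
entrant-level race data is not redistributable, so the published
cohort tables are not reproduced here.

Determinism: one root seed spawns independent per-modality streams;
identical config + seed gives byte-identical output.

## Numerical and design choices

- Problem sizes in the suite: full 947-runner fields for pipeline
  properties, 900 for parameter recovery (0.3 h noise; coefficients
  recovered within 3 SE, adjusted R² > 0.95), 2000 × 1000-resample
  null simulations for bootstrap calibration; the whole suite runs in
  seconds because resampling is vectorized.
- Degenerate inputs are flagged, not silently propagated: zero-variance
  differences in paired tests, constant samples in normality screens,
  perfect collinearity in VIF, zero-variance Bland–Altman differences.
- Rank-deficient regression designs raise an error naming the most
  collinear predictor pair.
- The interface is the library plus the numbered analysis drivers; the
  `trailpace` CLI wraps the same functions for shell use (simulation,
  feature building, comparisons, fitting, mid-race prediction).

## Limitations

The regression coefficients fitted on synthetic fields resemble but do
not equal the published ones (the generator is a structural emulation,
not a data reconstruction); replication mode exists precisely so the
published equations can be applied unchanged. Closed forms are provided
for ascent segments only. No multiple-testing correction is applied
across the comparison battery, matching standard practice in this
literature; interpret single p-values accordingly.
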