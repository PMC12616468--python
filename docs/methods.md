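# Methods

## The standardization model

The central modelling assumption is that a nutrient's concentration in an
edible plant part responds **linearly to atmospheric CO₂ concentration**
over the experimentally relevant range (roughly 310–750 ppm). Under that
assumption an observation pair measured at arbitrary levels (A, E) pins
down a whole response line, and the line can be read off at the standard
levels A\* = 350 ppm and E\* = 550 ppm to give a comparable effect size:

- Δ = (rE − rA)/rA, the relative change actually measured;
- L\* = ln[((E − A) + Δ(E\* − A)) / ((E − A) + Δ(A\* − A))], the log
  response ratio the same line implies between A\* and E\*.

L\* depends only on (Δ, A, E, A\*, E\*) — never on the units or magnitude
of the response — and equals ln(rE/rA) exactly when (A, E) = (A\*, E\*).
Both properties are enforced by tests (the scale-invariance property over
randomized inputs, and the identity over 10⁶ randomized cases at machine
precision).

350 ppm is a meaningful societal baseline (and sits inside the 310–455 ppm
spread of ambient levels in the experimental literature); 550 ppm is a
policy-relevant elevated level that most enrichment experiments meet or
exceed, so the elevated end of the adjustment is an interpolation. At the
ambient end the formula is applied uniformly even when A > A\* (a mild
downward extrapolation along the same line); if the real response saturates
below the experimental elevated level, the linear attribution
under-estimates the 350→550 effect, i.e. the estimate is conservative.

Degenerate inputs: the interpolated response must stay positive at both
standard levels; it is required to exceed 10⁻¹² × the measured span to
avoid taking logs of numerical zeros. In the vectorized table path such
rows are flagged (`excluded_crosses_zero`) rather than raising, and rows
with a zero elevated response are kept but excluded from log-ratio analysis
(`excluded_zero_response`).

## Weighted bootstrap inference

Groups are never normal or homoscedastic, so all inference is resampling
based. Per-entry variances are largely unreported in this literature, so
entries are **weighted by replicate count, not by inverse variance**:
a resample draws n entries with replacement with probability ∝ replicates,
and contributes its unweighted mean.

- **CI**: percentile interval (α/2, 1 − α/2) of the resample means with
  linear interpolation between order statistics. The simplest method
  consistent with a "95% mean effect size confidence interval"; BCa or
  basic intervals could be slotted in behind the same surface.
- **p-value**: Z = |weighted mean| / SE with SE the SD of the resample
  means; the null distribution recenters the sample at zero, resamples
  identically, and compares |Z\*| ≥ |Z_obs| (the absolute-value comparison
  makes the test two-sided). Zero-spread groups take the limiting values
  p = 0 (mean ≠ 0) or p = 1.
- **Power**: the sample is shifted by δ = ln(1 − 0.05) (a 5% decrease, the
  dominant direction of observed effects; the sign is configurable),
  re-bootstrapped on a fresh RNG substream, and power is the fraction of
  shifted resample means outside the original CI. At a vanishing shift
  this construction yields ≈ α by design.
- **Small-sample SD floor**: groups with fewer than 20 entries whose SD is
  below the whole-dataset SD (unweighted, over all standardized entries)
  have deviations around the shifted mean inflated to the dataset SD before
  resampling. Inflation preserves the resample's nonparametric shape while
  widening its spread. In the regime the floor is meant for — a shifted
  mean clearly outside the original CI — widening the spread can only move
  mass back toward the interval, so the floor is conservative (tested);
  if the shifted mean were inside the CI the same inflation could raise
  power, but that regime is not where the floor applies in practice. A
  zero-spread small group is replaced by a symmetric two-point sample at
  ± dataset SD around the shifted mean.
- **Determinism**: each group's seed is derived from the master seed plus a
  SHA-256 hash of the group key, then split into independent substreams
  for CI, p-value and power. Identical config and seed give bit-identical
  results regardless of group iteration order.

Power is classed low (< 0.4), medium (0.4–0.8, boundaries inclusive), and
high (> 0.8); forest-style reporting can drop rows at or below a power
floor (default 0.8) without altering retained values. Row color-coding
follows the p-value decision at α; a CI-excludes-zero flag is carried
separately for the occasional disagreement between the two.

## Partitioning rules

- **Tissue groups** are a fixed, user-extensible vocabulary: roots and
  tubers → belowground; grain, seed, fruit, fruit juice, pod →
  reproductive; shoot and stem → aboveground.
- **Nitrogen proxy**: nitrogen and (crude) protein are linearly related;
  the combined `N_proxy` stream takes the nitrogen record where present,
  else the protein record, never both for one data point (point identity:
  source × species × cultivar × tissue × CO₂ pair × timepoint). Originals
  stay available under their own codes.
- **Rice separation**: rice grains (flooded cultivation) can be held out
  as a stratum before any other split.
- Entries whose factor levels cannot be resolved go to an `unclassified`
  bucket that is reported but excluded from inference.
- Entry independence at curation: only the latest harvest
  (max `timepoint_rank`) of an experiment and only the primary edible part
  are retained; the filter is idempotent.

## Scenario projection

With effects linear in concentration, level C carries fraction
f(C) = (C − 350)/200 of the modeled 350→550 ppm effect; a pathway peaking
at concentration P avoids 1 − f(P) of it. Fractions are **not clamped**:
values below 0 (recovery below baseline) and above 1 (window exceeded) are
meaningful and left to the reporting layer to annotate. Partial effects
scale on the log scale before back-transforming to percent; for the effect
magnitudes involved this is indistinguishable from percent-scale scaling.
Built-in trajectories carry only published (year, ppm) anchors of the SSP
pathways; full curves are user-supplied CSVs.

## Publication-bias diagnostic

Effect size is plotted against replicate count (the only study-size proxy
consistently available; per-entry variances are incomplete in this
literature). The regression test fits effect ~ 1/√replicates by OLS with
heteroscedasticity-robust (HC3) standard errors — funnel spread shrinks
with study size by construction, so homoscedastic standard errors would
over-reject on perfectly unbiased data. This is an adaptation of the
classic small-study regression, and is labelled as such in output; it is a
screen, not a correction (no trim-and-fill or selection modelling).

## Synthetic data generator

The generator defines truth mechanistically on the response line in
concentration space: each group has a per-ppm relative slope s, the line is
anchored at 350 ppm (r(x) = r₃₅₀·(1 + s·(x − 350))), so the true
standardized effect is L_true = ln(1 + 200·s) at the default window. Per
entry it draws the ambient level uniformly over 310–455 ppm and the added
CO₂ from {150, 200, 300} ppm — mirroring the designs found in the
enrichment literature, where 200 ppm of added CO₂ is the most common
choice — perturbs the slope multiplicatively (sign-preserving log-normal,
SD τ) for between-entry heterogeneity, and applies independent
multiplicative log-normal measurement noise (SD σ) to both members of the
pair. Replicate counts are uniform integers over 3–8, matching the
observed average of roughly five to six replicates per entry. Defaults
τ = σ = 0.02 represent a moderately noisy but well-behaved literature.

What this emulates — heterogeneous (A, E) designs, group-structured linear
truths, replicate weighting, multiplicative noise. What it does not —
between-crop covariance, shared-study correlation between entries,
asymmetric (censored) reporting, real tissue/nutrient composition of the
published database. Passing recovery and calibration tests therefore show
the pipeline is correct under its own assumptions, not that the published
literature satisfies them.

## Problem sizes and numerical choices in the test suite

Tests that bootstrap use 2,000–10,000 resamples; the null-calibration study
uses 200 groups of 50 entries at 2,000 resamples and the recovery study 20
seeds at 100 entries per group — sizes chosen so the whole suite runs in
well under a minute while leaving Monte-Carlo error far below the asserted
tolerances. The tiny-sample bootstrap is checked against exact enumeration
of all 27 weighted resamples, with CI endpoints bracketed through the exact
CDF at 3 Monte-Carlo standard errors. Hypothesis property tests run
derandomized.

## Known limitations

- The linear-response assumption is untested above ~750 ppm and for
  saturating nutrients it biases effects toward zero (conservative).
- Replicate count is a coarse precision proxy; the size-bias regression
  has limited power against subtle selection effects.
- Cofactors (temperature, irrigation, sowing time, N/P/O₃ application) are
  stored and carried through but never analyzed.
- The bootstrap treats entries as independent after the curation filters;
  residual within-study correlation would narrow CIs artificially.
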