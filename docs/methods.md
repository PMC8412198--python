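# Methods

This note documents the models, numerical choices and simulator assumptions
behind `patcomm`, and what the test suite does and does not establish.

## GP models of pattern description

A pattern is a function sampled at 100 equidistant inputs on [0, 1]
(outputs are standardized to zero mean and unit variance before fitting;
canvas units are arbitrary). Patterns are modeled as draws from a zero-mean
GP whose kernel is either

* a **composition** of the three base kernels (linear, RBF, periodic)
  under SUM and PRODUCT, capped at three non-repeating components — 17
  canonical structures after flattening associative operators and sorting
  commutative children; the grammar includes both `(a·b)+c` and `(a+b)·c`
  nestings, since sums and products may be nested freely; or
* a **spectral mixture**, k(τ) = Σ_q w_q exp(−2π²τ²v_q) cos(2πτμ_q) with
  2 ≤ Q ≤ 6 components — the standard Gaussian spectral-density mixture.
  It is stationary, with k(0) = Σ_q w_q.

Model evidence is the log marginal likelihood, computed through a Cholesky
factorization of K + σ_n²I with a jitter of 1e−6 × the mean diagonal.
`log_marginal_likelihood` and `posterior_predict` are tested against dense
explicit-inversion oracles to 1e−8.

### Hyperparameter optimization

Positive parameters are optimized on the log scale with analytic gradients
(L-BFGS-B); the linear offset θ₁ is unconstrained. Restarts are drawn
log-uniformly from documented ranges (amplitudes and length-scales
0.05–5, period 0.05–1, noise variance 1e−4–1; θ₁ uniform on [0, 1]).
The marginal likelihood is highly multimodal in the period, so three
refinements are applied:

* the first restart uses mid-range values with the period set at the
  periodogram peak of the data, and half of the remaining restarts jitter
  around that peak (with occasional octave jumps);
* the period is bounded between twice the input spacing (below which the
  kernel aliases noise between samples) and five times the span (beyond
  which it degenerates into a smooth kernel the grammar already contains);
* after the best restart, a harmonic polish re-optimizes at half and double
  the fitted period, since any integer multiple of the true period explains
  periodic data.

Best-of-restarts wins; ties break by restart order, and across structures
by canonical grammar order. Fits are deterministic given the seed. A fit
whose restarts all fail is returned flagged, not raised.

### Component probabilities

The presence score of a base component divides the summed log marginal
likelihood of structures containing it by the sum over all structures.
This as-printed ratio is sign-sensitive (a warning is attached when the
log likelihoods mix signs); an exp-normalized alternative
(`mode="softmax"`), the posterior mass under a uniform structure prior, is
the mode used wherever a proper probability is needed (e.g. the
word-presence regressions).

## Stimulus generation and matching

Compositional stimuli draw a structure uniformly from the 17 and its
hyperparameters from the ranges above; spectral stimuli draw Q uniformly
from {2,…,6}. The spectral sampling ranges are chosen so both classes span
the same frequency and smoothness content (μ in 1–20 cycles per unit,
matching periods 0.05–1; bandwidths v in 0.003–10, matching envelope
correlation lengths of roughly 0.05–3): the comparison between the model
classes presumes equal expressivity, so neither class should be rougher by
construction.

Spectral entropy is the Shannon entropy of the normalized periodogram of
the mean-removed series (zero-frequency bin dropped, light 3-bin smoothing
to de-bias flat spectra), divided by log of the number of bins; constant
series score 0 by convention. Matched stimulus sets pair compositional
with noncompositional patterns greedily, minimizing the sum of z-scored
|entropy difference| and z-scored pairwise wavelet distance, until the
requested size (default 20 + 20 = 40) is reached.

## Reconstruction metrics

Drawings (≥ 5 dots) are resampled by a natural cubic interpolating spline
through every dot (duplicate x positions averaged with a warning;
constant-value extrapolation beyond the outermost dots) onto the
pattern's 100-point grid. Absolute error is the mean absolute pointwise
difference (a sum variant is available by flag). The wavelet distance
standardizes both series, pads to a power of two by edge replication, and
takes the Euclidean distance between Haar approximation coefficients at a
shared level — the smaller of the two series' deepest levels retaining
≥ 90% of energy, a symmetric rule that keeps the measure a true metric on
coefficient space. Standardization makes it invariant to positive affine
transforms of either series; constant series fall back to a zero vector
with a warning.

## The synthetic communication game

The simulator replaces the human describers, drawers and raters with a
known-ground-truth channel so every analysis stage is testable:

1. **Stimuli** — each game oversamples both generator classes and keeps an
   entropy/wavelet-matched subset (three compositional and three
   noncompositional patterns per describer by default), mirroring the
   matched-set study design.
2. **Descriptions** — word bags: each component present in the generating
   structure emits each of its ten vocabulary words with probability 0.4,
   plus Poisson(8) filler words. The built-in vocabularies are synthetic
   stand-ins with the flavor of human descriptions (wave/peak for
   periodic, line/slope for linear, smooth/curve for RBF). Spectral
   patterns emit only filler.
3. **Drawing** — the channel decodes the word bag into a structure
   (a component is flagged by any of its vocabulary words; flagged
   components combine by SUM; no flags fall back to RBF), fits that
   structure to a 20-point memory subsample of the original, and places
   5–30 dots (roughly evenly spread over canvas grid positions) on the
   posterior-mean reconstruction with vertical noise (sd 0.1). The
   `spectral-decoder` channel always fits a Q=3 spectral mixture; the
   `dot-noise-only` control skips decoding entirely and dots the original.
4. **Ratings** — each rater scores 30 drawings as
   clip(100 − 5 × wavelet distance + N(0, 5), 0, 100).

The memorability control redraws each pattern directly from a noisy copy
(no description), dotizes and resamples it, and averages wavelet distances
per pattern.

Defaults mirror the desk-scale study design (7 describers, 7 drawers,
6 patterns each split 3 + 3, 0–100 slider, ≥ 5 dots). What the simulator
does **not** emulate: natural-language syntax, judge ratings of
description quality, and human memory beyond the fixed subsample
bottleneck — so passing tests show the pipeline recovers planted effects,
not that humans behave this way.

## Linking regressions

The analysis table has one row per (pattern, drawer) pair with both
distances, mean rating, the best-grammar and spectral log likelihoods, the
three single-component log likelihoods, softmax component probabilities
and memorability; predictors are z-scored. Outcomes are regressed on
standardized log likelihoods in linear mixed models with a random
intercept and random slopes by participant group, estimated by REML for
coefficients and standard errors; a singular or non-convergent
random-slope fit falls back to a random intercept (flagged), and a
degenerate mixed fit falls back to OLS (flagged). Model comparison uses
BIC from an ML refit of the same structure,
BF_ab = exp((BIC_b − BIC_a)/2) — a deliberate approximation standing in
for full Bayesian mixed-model comparison, accurate to the sign/direction
level only. Comparisons are only made across identical random-effects
structures; mismatched fallbacks trigger a matched random-intercept refit.

Single-component controls regress the outcome on one component's log
likelihood (compositionality flag in the random part), then add the flag
as a fixed effect and report the Bayes factor for the addition. The
word-presence analysis fits a logistic model of composition-specific word
presence on the component probability with a random intercept over
describers (variational Bayes); the reversed direction — component
probability on presence, the other reading of the design — is available
by flag.

## Problem sizes used by the test suite

Desk-scale sizes keep the default run inside a few minutes while leaving
the statistical checks well-powered: oracle checks use 100 random cases;
structure recovery uses 15 patterns per base kernel at 2 restarts;
channel comparisons use 50 games at the default 7-describer size; the
planted-effect regression uses 20 seeds at n = 500 rows; stochastic
bounds are set so a correctly calibrated model fails with probability
below about 2%.

## Known limitations

* **Residual drawing-medium asymmetry.** The dot-noise-only control is
  meant to show that, with no model-based decoding, the two stimulus
  classes reconstruct equally well. In practice a residual difference of
  about −1.5 wavelet units (compositional easier) survives matching, about
  half the grammar-channel effect (≈ −3.5). The cause is measurable:
  dots-plus-spline reconstruction has a floor set by a pattern's
  finest-scale energy, and both matching criteria are blind to it —
  spectral entropy measures scale-free concentration, and the Haar
  approximation coefficients drop the finest detail band by construction.
  Spectral mixtures are broadband while compositions are often dominated
  by a single smooth component, so the classes differ at exactly the
  scales the criteria ignore. The corresponding control test is left
  failing rather than weakened; conclusions about the channel-driven part
  of the effect should rest on the difference between channels, not on
  the dot-noise control alone.
* The as-printed component-probability ratio is unstable when log
  likelihoods mix signs; use the softmax mode for downstream analysis.
* BIC Bayes factors ignore random-effect shrinkage subtleties; they are
  directional evidence, not calibrated posterior odds.
* The spline is an interpolant: with noisy dots it passes through noise.
  The wavelet distance at coarse levels absorbs much of this, the absolute
  error does not.
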