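# Methods

This note documents the models implemented in `easi-ms`, their assumptions,
the defaults that matter, and the numerical choices made where the design
was genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Spectral representation

All modeling operates on unit-resolution nominal spectra: centroided peaks
are rounded half-up to integer Da, intensities within a bin are summed
(conserving ion current rather than taking the maximum), and the binned
spectrum is normalised so its base peak is exactly 100%. Binning convention
is a package choice — EI quadrupole data are unit resolution and every
modeled channel is an integer, but no centroiding convention is imposed by
the method itself. Normalisation is idempotent and scale-invariant, so raw
instrument units never matter downstream.

Missing panel channels are true zeros, not missing data: the absence of an
expected fragment is evidence against an identification (the "reverse
search" logic of classical library matching).

## The per-ion linear models

For a panel of the K most abundant consensus channels (default K = 20,
including the base peak), each channel j is regressed on the other K − 1
channels over n training replicates:

    x_j = β_j0 + Σ_c β_jc x_c + ε_j

Selection is bidirectional stepwise least squares with partial-F tests:
enter the candidate with the smallest partial-F p-value if below `p_enter`
(default 0.05), then remove any included covariate whose p-value exceeds
`p_remove` (default 0.10), repeating until no change. These probability
thresholds are the standard stats-package reading of an "F-to-remove ≥ 0.1"
stopping rule; both are configurable. Direction (forward/backward/both) is
not dictated by the stepwise phrasing alone; bidirectional was chosen as
the least restrictive. Model R² above 0.9 for most panel ions is the
expected regime on replicate data and is asserted by the test suite on
generated training sets.

Numerical details:

* fits use `numpy.linalg.lstsq`; a candidate whose entry makes the design
  rank-deficient is refused and the search continues;
* zero-variance covariates (the base peak, fixed at 100) are excluded from
  candidacy; a zero-variance target yields a constant model with R²
  defined as 0;
* a visited-set guard terminates the (rare) enter/remove cycles;
* predictions are **never clipped** to [0, 100]: out-of-range predictions
  are precisely how non-matching spectra reveal themselves.

One caveat worth recording: with a single candidate covariate the null
false-entry rate equals `p_enter` exactly (the partial-F p-value is uniform
under H0), but with m candidates entry is governed by the *minimum* of m
p-values, so the empty-model rate under the null is roughly (1 − p_enter)^m,
not 1 − p_enter. The suite tests the single-candidate case, where the rate
is exact.

The consensus baseline predicts the training mean vector for every query;
because least-squares hyperplanes pass through the sample means, EASI and
consensus agree exactly on a query equal to the training mean.

## Comparison measures

MAR and Euclidean distance operate on residuals (predicted − measured);
cosine and the weighted match factor operate on the two vectors. The match
factor weights each channel as `max(A, 0)^x · (m/z)^y` with x = 0.6, y = 3
and multiplies the cosine of the weighted vectors by 999. Weighted cosine
(not squared cosine) is used; the printed near-ceiling thresholds of the
method's published applications are consistent with either, and plain
cosine keeps `score(a, a) = 999` an exact identity. Abundances are floored
at zero only inside this weighting, because fractional powers of negative
numbers are undefined; MAR, Euclidean and plain cosine use raw values —
the minimal intervention that keeps negative predictions informative.

`dot_product(a, a)` and `nist_score(a, a, …)` return their ceilings exactly
on bit-identical inputs (a perfect match *is* the ceiling by definition;
floating-point cosine of a vector with itself can otherwise land 1 ulp off).

## Mahalanobis distance and the outlier test

The covariance model drops zero-variance channels (19 retained of a
20-channel panel whose base peak is constant), stores the training mean and
sample covariance (n − 1 denominator), and computes
`d = sqrt((x − x̄)ᵀ C⁻¹ (x − x̄))` via a Cholesky factorisation; an explicit
inverse is never formed. With fewer rows than retained channels + 1 the
sample covariance is singular; the fit warns and enables a pseudo-inverse
fallback. Useful identities asserted by the suite: training rows sit at
mean squared distance K(n−1)/n from their own model, and the distance is
invariant under any invertible affine map applied to both training set and
query.

The chi-square outlier test compares d² to the 1 − α quantile at df equal
to the retained channel count (default df = 19, α = 0.05, critical value
30.14). This is conservative: squared Mahalanobis distances to an
*estimated* mean and covariance are only asymptotically chi-square.

## Threshold classifiers

Similarity polarity predicts positive when score ≥ threshold; dissimilarity
when score ≤ threshold (inclusive on the positive side for deterministic
tie behavior). ROC curves sweep all distinct scores plus a predict-nothing
sentinel; the trapezoid AUC is then *exactly* the Mann–Whitney pairwise
ordering probability with ties counted ½, which the suite verifies against
a brute-force O(n²) oracle. Precision–recall points with zero predicted
positives are omitted (precision undefined).

The zero-false-positive threshold is placed at the midpoint between the
extreme known-negative score and the nearest known positive on the
admissible side; if no positive is admissible the threshold sits one ulp
beyond the extreme negative and TP = 0. Midpoint placement is a package
choice — any threshold strictly between the two scores yields the same
confusion matrix on the observed data; the midpoint maximises the margin to
both.

## Supervised residual logit

The stepwise logistic regression on EASI residual channels uses
likelihood-ratio (not Wald) entry/removal tests — they remain directional
under separation — with the same 0.05/0.10 thresholds. The response is
coded 1 for known negatives, so low fitted probability means "target
compound" and the decision rule is p < 0.5, with the exact boundary
classified negative.

Complete separation is the *expected* outcome on well-resolved
diastereomers, and there the unpenalised maximum-likelihood estimate does
not exist. Whenever the fitted hyperplane perfectly separates the training
classes (or the Newton iteration fails to converge), the final model is
refit with a ridge penalty (`ridge_alpha`, default 1.0, intercept
unpenalised) and tagged `"ridge"` in the output. The in-package
Newton/IRLS fitter is cross-checked against `statsmodels.Logit` on
non-separated data in the test suite.

## The synthetic-data generator

The generator emulates the statistical structure the method assumes, not
the physics of fragmentation. Each replicate draws a scalar latent factor
E ~ N(latent_mean, latent_sd²) — an effective internal-energy /
instrument-state axis — and sets each channel's raw intensity to
`α_i + b_i·E + noise`, floored at 0, with additive Gaussian noise. Defaults,
chosen once as the study conditions:

* 20 cocaine-like channels (82, 182, 94, 96, 105, 77, 152, 155, 198, 272,
  303, …); intensity values are arbitrary and labeled as such;
* the base-peak channel (82) has slope 0, so normalisation divides by a
  near-constant and the normalised abundances remain linear in E;
* 17 channels share the slope sign and two (77, 105) anticorrelate; with
  latent sd 1 and raw-unit noise sd 2 (≈0.2% of base peak) the median
  pairwise inter-ion correlation on 128 replicates exceeds 0.9, matching
  the regime reported for real replicate EI spectra;
* lab shifts move `latent_mean` by a multiple of the training latent sd;
* diastereomer-like negatives multiply the first channel of designated
  pairs by a ratio-shift factor (defaults: 94/96 × 0.6, 152/155 × 1.5),
  sharing every channel with the positives;
* distinct negatives reuse the channel list with the intensity assignment
  reversed and an independent latent factor — decorrelated from the
  positive pattern while keeping all panel channels present, as real
  unrelated drugs share low-mass fragments;
* training size 128 and quick-start size 30 follow the reference workflow.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: isotope patterns, chromatographic or background
interference, concentration/matrix effects, multi-dimensional instrument
state (a single latent factor makes inter-ion structure exactly rank-one up
to noise), and heavy-tailed or multiplicative noise. Results on synthetic
data demonstrate correctness of the machinery and the *qualitative*
EASI-over-consensus ordering, not casework error rates.

## Problem sizes

The test suite and acceptance script run at desk scale by design: training
sets of 128 replicates (the reference workflow's size), query batches of
10–60 spectra, 100-seed Monte-Carlo loops for the selection/recovery and
dominance properties, and 1000 random vector pairs for metric-oracle
equivalence. These sizes keep every statistical assertion comfortably
resolvable while the whole suite completes in well under a minute of pure
computation per heavy test.

## Known limitations

* Stepwise selection inherits the usual post-selection caveats; reported
  R² and residual SD are in-sample and not selection-adjusted.
* The chi-square outlier test ignores estimation error in C (no Hotelling
  T² correction), as conservative df compensates in the intended regime.
* Score-to-likelihood-ratio calibration (kernel-density overlap of score
  distributions) is out of scope.
* The CLI scores one metric set per invocation; library users can of
  course combine metrics arbitrarily.
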