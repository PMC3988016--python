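# Methods

`gazecond` quantifies how image content and behavioral relevance predict
human fixations. This note documents the model, its estimators, the
numerical choices, and what the synthetic studies do and do not show.

## The conditional-probability saliency model

For a subject *s* and image *i*, the saliency of a feature is the
conditional probability of fixation given the feature's percentile *X*:

    p(fixation = 1 | X) = p(X | fixation = 1) · p(fixation) / p(X)

Feature maps are first remapped to percentiles by **weighted histogram
equalization**: the percentile of a pixel is the weighted fraction of
pixels with smaller feature values (ties take the midpoint rank), where
the weights are the subject's *control fixation density* — their
fixations on all **other** images of the category, smoothed with a 1°
FWHM Gaussian. Under these weights p(X) is uniform by construction, so
the saliency function reduces (up to the constant p(fixation), which we
drop) to the histogram of percentiles at actually fixated locations.
The weighting is the central-bias correction: a purely spatial fixation
bias, combined with any spatial gradient of the feature, produces a
flat percentile distribution at fixations and therefore no spurious
saliency.

In two dimensions (8×8 bins; 64 bins in 1D) the joint control
distribution p(X₁, X₂) is *not* uniform — intrinsic correlations
between features survive equalization of the marginals — so it is
estimated from control-weighted pixels and divides the joint histogram
at fixations.

Deviation between actual and control distributions is scored with the
symmetric Kullback–Leibler divergence in bits (Jeffreys divided by two):

    D(P, Q) = ½ [ Σ P log₂(P/Q) + Σ Q log₂(Q/P) ]

computed per subject after averaging the per-image distributions within
subject, then averaged across subjects; confidence intervals are a
percentile bootstrap (1000 resamples) over the per-subject values.

**Practical upper bound.** The fixation map of an image, pooled across
subjects, is itself treated as a feature and pushed through the same
equalize → saliency → divergence pipeline. It stands in for the best
image-derived predictor; no battery feature can systematically beat it.
On synthetic data this bound is checked against the battery features,
not against the planted generator field: when the planted field *is*
the true sampling density, the empirical (noise-limited) fixation map
can score below it, which is a statement about map estimation noise,
not about the bound's logic.

## The feature battery

Fifteen maps per image, all computed from a cone-opponent conversion of
the RGB stimulus (linearized sRGB → LMS via Hunt–Pointer–Estévez with
rows normalized so gray maps to L=M=S; luminance L+M+S, red–green L−M,
yellow–blue (L+M)/2 − S, saturation √(rg² + yb²)):

* **Local means** — LM (0.5°), RGM/YBM (2°), SATM (1°): circular-aperture
  means; aperture diameters round to the nearest odd pixel count and
  shrink at borders to in-image pixels (no padding is invented).
* **Local contrasts** — LC/SATC (1°), RGC/YBC (2°): population standard
  deviation over the same apertures; TC (3.7°) is the std of the LC map
  ("contrast of contrast"). Implemented by FFT convolution with an
  explicit disk footprint; the second moment is computed on the
  globally centered channel to avoid cancellation.
* **Intrinsic dimensionality** — S/E/C from the gradient structure
  tensor (pre-smoothing 0.13° std; tensor integration under a Gaussian
  patch of 6° extent, 1° std). With eigenvalues λ₁ ≥ λ₂ and trace t,
  S = τ/(t+τ), E = (λ₁−λ₂)/(t+τ), C = 2λ₂/(t+τ): a barycentric
  decomposition (nonnegative, sums to 1) where τ = 10⁻³ of the image's
  maximum trace. A uniform image scores S = 1 exactly. The τ floor
  keeps the ratio defined in flat regions; the `corner` test pattern is
  a four-quadrant junction so both edges are full lines and the
  cornerness peak is symmetric about the junction.
* **Phase symmetry** — Kovesi-style phase congruency from log-Gabor
  quadrature pairs (3 scales spaced ×2.1, bandwidth σ_on_f = 0.55,
  6 orientations; the "high" and "low" bands differ by a factor-4 shift
  of the shortest center wavelength, 0.25° vs 1°). Per orientation the
  symmetry energy is Σ_scales (|even| − |odd|), floored by a noise term
  proportional to the image-wide mean amplitude and normalized by the
  amplitude sum. **Bilateral** symmetry sums energies over
  orientations; **radial** symmetry takes the *minimum* over
  orientations — a center of radial structure is even-symmetric along
  every direction, whereas ridges and edges are even along at most one,
  so the minimum isolates ring/blob centers. Images are padded with a
  linear ramp to their mean before the FFT so the periodic extension
  has no wrap-around discontinuity.

Heavy ties (e.g. symmetry maps that are exactly zero over most of a
noise image) make the percentile distribution of a map non-uniform even
after equalization; the 1D control distribution is therefore estimated
from the weighted percentile histogram of the map itself rather than
assumed uniform. For tie-free maps the two coincide.

## Integration and the interest model

Two-dimensional saliency functions are fit by least squares from their
1D marginals, `s ≈ c + a·m₁ + b·m₂ (+ γ·m₁m₂)`; goodness of fit is the
squared Pearson correlation over populated bins (empty joint bins are
masked, never imputed), which makes r² invariant to affine rescaling of
the surface. Sub/supra-additivity is the joint divergence as a
percentage of the sum of the two 1D divergences (both at the 8-bin
resolution). A duplicated channel lands at 50% up to an exact
pseudo-count scaling factor (≈49.3% at the study sizes used): the joint
estimate shares its diagonal with the 1D histogram and the off-diagonal
regularization mass cancels between P and Q.

The interest model `saliency ≈ c + α·Iˣ + β·Fˣ` is fit on bin-center
percentile axes rescaled to [0, 1], for exponents x ∈ {1, 2, 4}
(a small grid, not a continuous fit). The quarter decomposition splits
both axes at the 50th percentile and reports the percentage of total
saliency mass per quadrant.

## Temporal and duration analyses

The per-rank time course restricts both the actual fixations and the
controls to a single rank r (controls from rank-r fixations on other
images), because the central bias is strongly rank-dependent. Rank-1
fixations are excluded throughout: the first "fixation" after stimulus
onset is the pre-trial central drift-correction point. Ranks with fewer
than 50 events are dropped; the curve is also reported normalized to
its peak.

Durations are z-scored per subject × category with the population-SD
convention (constant groups get z = 0 with a warning). The joint
duration surface bins mean z by (interest, feature) percentile; the
plane fit uses the raw per-fixation regressors in percentile units
(0–100) per subject. Because the z-transform is affine and invertible
per subject, fitted slopes are also reported back on the native scale
(ms per percentile) by multiplying with the subject's duration SD;
planted generator weights are recoverable on that scale without the
shrinkage the z-normalization would otherwise impose.

## The synthetic-data generator

The generator produces every input the pipeline consumes, with known
truth:

* **Pink-noise stimuli** — a target amplitude spectrum (1/f^γ or an
  arbitrary per-channel spectrum) combined with the phase of a
  white-noise image's Fourier transform (amplitude discarded), inverse
  transformed per channel and rescaled to [0, 1]. Conjugate symmetry of
  the phase guarantees a real image; the pre-rescale field has zero DC.
* **Observers** — fixations sampled from `central_bias(x) ·
  g(percentile(x))` (isotropic Gaussian bias, default σ = 5°, or
  uniform; g on [0, 100]); ranks assigned sequentially within trials,
  rank 1 pinned to the image center to emulate the drift-correction
  artifact. Durations follow `base + w_I·I + w_F·F + σ·ε` (ms;
  I, F percentiles; base 302 ms). A per-rank schedule of g functions
  supports the temporal scenario.
* **Clicks** — exactly 5 per synthetic rater (35 raters) from a
  Gaussian mixture at planted interest centers; out-of-bounds draws are
  redrawn.

**Study conditions.** Scenarios use 192×192 px images at 16 px/deg
(12°×12°), 4 observers, and 6 images per category — 16 for the
interest/duration studies, where the leave-one-image-out control
weighting must be stable: with too few images the control density is
dominated by the other images' interest loci and the equalization axis
warps, attenuating recovered weights (the original study had 64 images
per category). Planted interest centers are uniform over the image so
the pooled control density is spatially unbiased, matching the
generative model the estimator assumes. Event counts are 5·10⁴
(calibration/recovery scenarios) and 10⁵ (interest/duration).

**What passing these studies does not show.** The generator plants
smooth scalar fields, isotropic biases, independent feature/interest
maps, and linear or power-law saliency — real images have correlated
features, object structure, anisotropic bias, and the generator's
pink-noise fields have no semantic content. Recovery under these
conditions validates the estimators (calibration, bias-correction,
parameter recovery), not any claim about real gaze data.

## Numerical choices and edge cases

* Percentile ties take midpoint ranks; a constant map equalizes to 50
  everywhere with a warning.
* Histograms get a pseudo-count of ½ event per bin before
  normalization; weighted (control) histograms are rescaled to the
  actual event count first so the regularization strength matches.
* `symmetric_dkl` is computed as ½ Σ (P−Q)(log₂P − log₂Q): termwise
  nonnegative and bit-exact under argument exchange; bins empty on one
  side only are floored at 10⁻¹² (never infinite), bins empty on both
  sides contribute nothing.
* Density maps use `reflect` boundary smoothing, which conserves each
  event's mass and makes map construction exactly linear in events.
* Null-calibration flatness is judged per bin against the binomial
  standard error, with the count of >3 SE exceedances compared to the
  null's own 99.9% envelope (with ~10³ bins a handful of 3-SE
  excursions is expected under perfect calibration).
* Every stochastic routine takes an explicit seed or `Generator`;
  scenario RNGs derive from (seed, CRC32 of the scenario name).

## Known limitations

* The sRGB→LMS matrix is a documented convention, not the (unstated)
  calibration of the original recordings; all opponent-plane results
  are invariant to monotone channel rescalings only after equalization.
* Phase-symmetry constants (scales, orientations, noise floor) are
  package conventions; only the low/high band distinction and the
  radial/bilateral split are contractual.
* The practical upper bound inherits estimation noise of the fixation
  map; with few events per image it is conservative (see above).
* Bootstrap CIs resample subjects only; with the 4 synthetic observers
  they are coarse and are reported for structure, not inference.
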