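# gazecond

Analysis pipeline for **overt visual attention**: how much do low-level
image features and behaviorally relevant "interestingness" each
contribute to where (and for how long) people fixate when freely
viewing images?

The package is written for eye-movement researchers. It implements:

* a **15-map feature battery** over a cone-opponent (DKL-style) color
  representation — local intensity and contrast of the luminance,
  red–green, yellow–blue and saturation planes, texture contrast,
  intrinsic dimensionality (surfaceness / edgeness / cornerness from
  the gradient structure tensor), and radial/bilateral phase symmetry
  from log-Gabor quadrature filters;
* **Bayesian saliency functions** p(fixation | feature = X): feature
  maps are histogram-equalized to percentiles under the weights of a
  *control* fixation density (the subject's fixations on all other
  images of the category), which makes p(X) uniform and corrects the
  central bias; the saliency function is then the percentile histogram
  at actually fixated locations, in 1D (64 bins) or jointly in 2D
  (8×8 bins, where the control distribution keeps the intrinsic
  correlation between features);
* **symmetric Kullback–Leibler scores** in bits,
  D = ½[Σ P log₂(P/Q) + Σ Q log₂(Q/P)], per subject with percentile
  bootstrap CIs, plus the *practical upper bound* obtained by treating
  the actual fixation map itself as a feature;
* **integration models** (additive and interaction fits of 2D saliency
  from its marginals, sub/supra-additivity as a percentage of the
  additive prediction, quarter decomposition, and the
  alpha*Interest^x + beta*Feature^x model over an exponent grid);
* **temporal and duration analyses** (per-rank D_KL time courses with
  rank-matched controls; z-scored fixation durations as a joint
  function of interest and feature percentiles);
* a **synthetic-data generator** (pink-noise stimuli with exact target
  amplitude spectra, planted-saliency observers with central bias,
  click cohorts, planted duration models) so the whole pipeline is
  validated against known ground truth without any external data.

## Worked example

Plant a linear saliency g(X) = X on smooth random fields, sample 5·10⁴
fixations from four synthetic observers, and recover the saliency
function through the full pipeline:

```python
from gazecond.scenarios import end_to_end_recovery

report = end_to_end_recovery("linear", seed=1)
print(round(report["saliency_vs_planted_r2"], 3))   # 0.996
print(round(report["fraction_above_median"], 3))    # 0.752
print(round(report["dkl_bits"], 3))                 # 0.325
```

The estimated saliency function tracks the planted line (r² = 0.996),
and the fraction of fixations above the median percentile is 0.752 —
sampling with probability proportional to percentile puts
∫₀.₅¹ 2u du = 3/4 of fixations above the median. The same harness
exposes `"null"` (calibration: every battery feature scores
< 0.005 bits), `"central_bias"` (the control weighting drops a spurious
0.065 bits to 0.004), `"interest"` (recovers a planted
interest-to-feature weight ratio of 4.57 at 4.48),
`"rank"` and `"duration"` scenarios.

The numbered scripts under `analysis/` run these studies end to end and
write their tables to `results/`:

```sh
python analysis/01_simulate_studies.py
python analysis/03_saliency_dkl.py
...
```

## Layout

```
src/gazecond/     library: geometry, color, features, symmetry,
                  equalize, gaze, saliency, integration, temporal,
                  synth, scenarios
analysis/         numbered narrative drivers writing results/ tables
tests/            pytest suite (unit, property and end-to-end checks)
scripts/          acceptance.py
docs/methods.md   model, estimators, numerical choices, limitations
```
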