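# Methods

## The encoding model

The pipeline assumes delay-period alpha-band power at each sensor is a
linear mixture of *l* = 8 latent location channels. Each channel has an
idealized circular tuning curve, a half-wave rectified and squared
sinusoid `b_k(θ) = [max(0, cos(θ − c_k))]^p` with centers every 45° and
exponent *p* = 2. The exact sinusoid form is a modeling choice; the
rectified-squared family was chosen because at even *l* it forms an
exact partition (Σ_k b_k = l/4), which gives closed-form oracles for
testing. The 16 stimulus locations are mapped onto the 8 channels by
evaluating each trial's own 22.5°-resolved angle on the basis, which
merges adjacent location pairs symmetrically rather than by hard
binning.

Weights solve `C₁ ≈ W B₁` by ordinary least squares with **W** of shape
l × m, the only orientation consistent with the decoding step
`Ĉ₂ = W B₂`. When the training Gram matrix `B₁B₁ᵀ` is rank deficient —
unavoidable for noiseless synthetic data, whose sensor power lives in an
l-dimensional subspace of the m sensors — `fit_weights` returns the
minimum-norm least-squares solution (`numpy.linalg.lstsq`) instead of
raising; an optional ridge term is available when explicit
regularization is preferred. The residual-orthogonality property of OLS
is tested directly.

Cross-validation is stratified sixfold: within each location, trials are
shuffled under the run seed, any remainder beyond a multiple of six is
dropped (the count is reported), and the rest are spread evenly so every
fold samples every location equally. Each trial is decoded exactly once
by weights fit on the other five folds; with a time axis present,
weights are fit independently per time bin with no temporal smoothing.

## Alignment and the tuning magnitude

Decoded vectors are circularly rotated by whole channel steps so each
trial's nearest basis center sits at 0° offset; angles exactly halfway
between two centers are assigned to the counterclockwise (lower-angle)
center, deterministically. Because rotation is by integer steps there
is no interpolation, and the multiset of decoded values per trial is
preserved (tested as an invariant). The offset axis runs −180°…+180° in
45° steps with the two endpoints identified as one circular bin.

The scalar tuning magnitude is the mean response at offsets
{−45°, 0°, +45°} minus the mean at {135°, ±180°, −135°}. It is zero for
a flat curve, invariant to additive constants, and evaluates to 2/3 for
the noiseless centered basis curve. It is one reasonable
operationalization of "tuning strength"; results do not hinge on the
choice because group inference runs on the full offset maps.

With 16 locations on 8 channels, half the trials sit 22.5° from their
assigned center, so the exact noiseless aligned curve is the mean of the
centered basis function and its 22.5°-shifted copy — slightly
asymmetric toward positive offsets by the tie-break. The exact-recovery
tests assert this analytic mixture, and the pure centered curve on the
on-center trial subset.

## Activation patterns

Raw decoding weights may encode suppression of correlated noise rather
than signal topography. The forward-model patterns are
`A = cov(B₁) Wᵀ cov(Ĉ₁)⁺`, the regression of sensor data on decoded
responses. The decoded covariance is inverted on its principal subspace
only: eigendirections below 5% of the dominant eigenvalue are truncated
(with a warning). This matters here because the basis covariance is
intrinsically rank-6 (the curves sum to a constant, and their harmonic
content vanishes at the fourth circular harmonic) with a ~25:1 spread
across the remaining eigenvalues; a plain inverse amplifies exactly the
directions dominated by in-sample overfitting noise. With the truncated
inverse, patterns recover the true mixing's column space markedly
better than transposed weights under strong shared (low-rank) noise,
which is the property the test suite asserts.

## Spectral analysis

Power is estimated per trial by a sliding tapered FFT: 500 ms Hann
window advanced in 50 ms steps, giving 2 Hz frequency resolution and
window centers reported on the epoch time axis. Windows are placed only
where fully inside the epoch (no zero padding). Power is one-sided and
coherent-gain corrected so a unit sinusoid at a bin center yields
exactly 0.5; the periodic Hann taper leaks a further 1/4 of that power
into each adjacent bin and nothing beyond, so the alpha-band mean over
the {8, 10, 12} Hz bins of a 10 Hz carrier is exactly half its
single-bin power — the closed form the synthetic cross-module tests
use. A frequency bin belongs to a band when its center lies in the
closed interval; power is analyzed linearly (no log transform) by
default. Band and window averaging raise informative errors naming the
empty axis when a selection misses.

## The synthetic cohort

The generator emulates the study conditions the analysis assumes: 30
subjects; 16 equally spaced locations × 40 trials (640 per subject) with
congruency balanced within location; 8 latent channels mixed into 32
sensors (each sensor weakly driven by all channels plus one preferred
channel, full column rank enforced); delay window (−1, 0) s and precue
baseline (−4, −3) s on an epoch locked to target onset. During the
delay, latent channel k carries `baseline_power · (1 − d·b_k(θ))` —
multiplicative depression of the attended location's generators, depth
d drawn per subject from U(0.2, 0.8); outside the delay there is no
location dependence. Sensor power adds independent Gaussian noise
(SD 0.5 on a baseline of ~1–2 a.u. per sensor) and is clipped at zero.
The time-series front end gives each channel a 10 Hz carrier with
independent per-trial phase and envelope `sqrt(2g(t))`, so expected
band power reproduces the power-domain rule; phases being incoherent,
per-trial interference between channels adds realistic multiplicative
power noise.

Behavior: RT = 500 ms + flanker cost on incongruent trials + Gaussian
noise (SD 40 ms), with cost `max(0, 80 − 80·d)` ms — deeper tuning,
smaller cost, producing the negative across-subject linkage. The
magnitudes sit in the usual flanker-paradigm range (tens of
milliseconds). The sustained-tuning variant marks each trial latently
sustained with probability 0.5; non-sustained trials lose their tuning
from −0.5 s onward and incur a 60 ms RT penalty, creating the
within-subject link between tuning sustainability and speed that the
median split recovers.

What the generator does not emulate: real sensor geometry or head
physics (sensors are treated as power-positive combined channels), 1/f
background spectra, eye movements, trial-count attrition, or temporal
autocorrelation of attention. Passing tests therefore demonstrate the
correctness and calibration of the analysis under its own assumptions,
not robustness to every property of real recordings.

## Statistics

Flanker effects use correct trials only (standard practice); Cohen's
*d* is the RT difference over the two conditions' pooled SD. The
correlation map defaults to *d* as the behavioral covariate with the
raw RT difference available by flag.

Cluster inference: cell statistics (across-subject t against zero, or
across-subject Spearman rho) are thresholded two-sided at the critical
value for p = .05 at the available n; clusters form by adjacency of
time neighbors (±1 bin) and offset neighbors (±45° with circular
wraparound; ±180° is a single bin, so no cluster can split at the wrap
— asserted on a planted wrap-spanning effect). Cluster mass is the sum
of the statistic; each observed cluster's |mass| is referred to the
Monte Carlo null of the maximum |mass| under sign flipping (paired) or
behavior relabeling (correlation), with p = (1 + #{null ≥ obs}) /
(1 + n_perm), which is exact-conservative and bounded away from zero.
Family-wise error calibration is verified empirically (500 null
datasets). The median split is computed within each location: trials
sorted by RT (stable on trial order) split at the middle, ties at the
boundary and odd-count remainders going to the slow group — which also
yields equal halves when all RTs tie.

## Problem sizes and numerical choices

The test suite runs cohorts at the study scale (30 subjects, 640
trials) for the recovery properties, with 500-permutation cluster
tests and 20 replicate cohorts per property; the depth-monotonicity
sweep uses 6-subject cohorts per replicate, and the calibration check
uses 500 pure-noise datasets of 20 subjects on 16 × 8 maps. The
acceptance script runs one full 30-subject study per analysis at 1000
permutations. Degenerate inputs fail loudly: locations with fewer
trials than folds, empty band/window selections, missing congruency
conditions, and non-uniform time axes all raise with the offending
axis or location named; all-subthreshold maps return an empty cluster
list rather than erroring.

## Known limitations

- The decoded-covariance truncation level (5%) is a fixed default; very
  different basis families may need a different cutoff.
- The generator's multiplicative-depression rule is one plausible
  mapping from attention to alpha power; the pipeline itself is agnostic
  to the generative form, but recovery guarantees are only tested under
  this rule.
- Sensor-space spatial cluster inference (over real sensor layouts) is
  out of scope; cluster tests operate on time × offset maps, and the
  hemifield power contrast is provided descriptively
  (`attention_contrast`).
- No eccentricity dimension: tuning is over polar angle only.
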