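# Methods

## The model

The classifier is a two-stage convolutional network mapping a short
motion sequence (32 x 32 px, 6 frames, intensities in [-1, 1]) onto one
of 64 velocity classes, the Cartesian product of 8 directions (4
cardinal, 4 oblique) and 8 linearly spaced speeds from 0.8 to
3.8 px/frame.

* **V1 stage.** A bank of 3D kernels (6 x 6 px x 6 frames) applied at
  every valid spatial position (valid convolution, 27 x 27 positions),
  plus a per-kernel offset, followed by half-wave rectification.  At the
  reference width of 128 kernels this stage carries 27,776 learnable
  parameters and 20,155,392 input connections.
* **Pooling.** A stride-1 average-pooling window (11 x 11) reduces each
  map to 17 x 17, giving 36,992 units.  With pooling enabled the readout
  carries 36,992 x 64 = 2,367,488 weights (+64 offsets).  A no-pooling
  mode is provided.
* **MT stage.** A linear readout onto 64 units followed by softmax; the
  predicted class is the most active unit (ties resolve to the lowest
  index).  Unit (i, j) on the direction-major grid is labelled with
  direction 45 i degrees and speed 0.8 + 0.43 j px/frame.

Training is plain mini-batch stochastic gradient descent (batch 100) on
the categorical cross entropy, with a constant learning rate, no
momentum and no weight decay.  Convolutional weights are initialised
from N(0, 0.001^2); readout weights and all offsets start at 0.  The
corpus is reshuffled every epoch under the run seed.

The convolution and its gradients are evaluated spectrally (rfft2 per
frame with a per-frequency contraction over frames); an im2col direct
summation implementation is retained and the two are held equal in the
test suite, alongside a central-finite-difference check of every
gradient.  Pooling and its adjoint are banded matrix products.

## Synthetic training worlds

The corpus generator replaces photographic material with textures whose
controllable statistics isolate the two properties the analyses rest
on:

* **Spatial autocorrelation.**  Sources are Gaussian noise fields shaped
  to a 1/f^a amplitude spectrum (default a = 1, the natural-scene
  slope).  Autocorrelated sources make spatiotemporal contrast (the SD
  of all pixels in a sequence) grow with translation speed — the
  speed-contrast association; white noise (a = 0) abolishes it.
* **Orientation anisotropy.**  The spectrum is multiplied by
  1 + (r - 1) cos^2(2 phi) across frequency angle phi, making cardinal
  orientation energy exceed oblique by the factor r (default 2, a
  moderate photographic excess).  The anisotropy axis can be rotated by
  45 degrees to put the excess on the obliques.
* **Contrast normalisation.**  Each source is scaled to a pinned RMS
  contrast (0.3) and clipped to [-1, 1], so that per-sequence contrast
  variation reflects content and motion rather than source diversity;
  the ``contrast_range`` field widens this into a distribution when
  photographic contrast spread is wanted.  A dead-leaves texture model
  (occluding elliptical leaves with a power-law size distribution,
  sharp occlusion edges) is available as an alternative source model.

Sequences are cut by rigidly translating a 32 x 32 window across the
source at the class velocity with bilinear subpixel interpolation
(a Fourier-shift sampler is available); every class, cardinal and
oblique, requires subpixel rendering, so interpolation artifacts cannot
act as a direction cue.  Dot worlds (1-10 dots of random diameter and
contrast on a mid-grey background, translating without wraparound)
provide an orientation-free control; distorted variants stretch each
dot to a 4:1 aspect ratio aligned with the cardinal or oblique axes.

Corpus manipulations: `reverse_speed_contrast` rescales each sequence
about its mean so the mean contrast of each speed class is mirrored
across speed rank (flipping the speed-contrast correlation);
`blur_or_sharpen` convolves frames with a Gaussian (SD 20 px) or its
unsharp-mask complement, raising or lowering spatial autocorrelation;
speed-world corpora tilt the class counts linearly so the slowest class
holds twice the sequences of the fastest (or the reverse), keeping
directions balanced.

What the generator does **not** emulate: the sparse, phase-aligned edge
and object structure of photographs (Gaussian textures have random
phases), scene segmentation, and luminance nonstationarity.  This
matters for generalisation: networks trained on these textures classify
held-out textures well but transfer to pure sinusoidal gratings far
more weakly than a fully trained photographic network would (see
Limitations).

## Desk-scale study conditions

All trained-network results are computed at desk scale: 32 kernels, 50
sequences per class (3,200 sequences; 70/15/15 split), 200 epochs.
Replicate and manipulation networks use 16 kernels, 16 sequences per
class and 80 epochs; the reverse-contrast network in the reproduction
script trains for 150 epochs (its offset parameters freeze once the
training loss saturates, around epoch 100, and the resulting
correlation is unchanged by further training).  At the reference scale
(128 kernels, 1,000 sequences per class, 2,500 epochs) the printed
learning rate 1e-4 is appropriate; a desk-scale run performs ~250x
fewer gradient updates, and at 1e-4 never leaves the small-weight
regime of the initialisation.  Scaled runs therefore use a larger
constant rate (default 0.25), chosen as the largest value that trains
stably on the default corpus; the rate is held constant throughout, as
at full scale.

## Decoding

Continuous direction is read from the 64-unit response by fitting

    G(x) = p + A exp(kappa (cos(x - x0) - 1))

to the 8 direction-labelled activations at the best-responding speed
and reporting x0 (width sigma = 1/sqrt(kappa)); continuous speed by the
Gaussian analogue over the 8 speed-labelled activations at the best
direction.  Failed or modulation-free fits fall back to the circular
mean (flagged).  For population decodes a parametric stimulus is
presented at all 8 trained directions, responses are rotated onto a
common axis and averaged before fitting.

For the direction experiments (plaid speed-ratio, unikinetic,
contrast-ratio and rhombus series) each stimulus is additionally
presented at all 8 trained directions with responses rotated back onto
a common axis and averaged before fitting.  This population alignment
cancels the network's own direction anisotropy, which at desk scale
otherwise contributes a systematic decode offset of order 15 degrees.

Psychometric data (k successes of n at each level) are fit by maximum
likelihood with a cumulative Gaussian carrying a symmetric guess/lapse
rate (bounded at 0.2).  The threshold (PSE) is the 50% point mu; the
JND is taken as sigma (the 50-to-84% distance) and sensitivity as
1/JND.  Step-function data pin sigma at its floor and are flagged
degenerate.

## Analyses

* **Tuning maps.**  Drifting sinusoids at 8 directions x 8 spatial
  frequencies (log-spaced 2-64 px/cycle) x 8 temporal periods
  (log-spaced 2-64 frames/cycle), each averaged over 32 evenly spaced
  start phases; preferences are argmax responses.  Temporal frequency
  is parameterised as a period because values above half a cycle per
  frame alias on a 6-frame input.
* **Pattern vs component.**  Grating and 90-degree-plaid responses over
  16 directions at the unit's preferred speed; the ideal pattern
  prediction is the unit's own grating tuning, the component prediction
  the mean of that tuning shifted by +-45 degrees.  Partial correlations
  R_p = (r_p - r_c r_cp) / sqrt((1-r_c^2)(1-r_cp^2)) (and symmetrically
  R_c) are compared by one-sided Fisher z tests (n = 16, alpha = 0.05):
  a unit is component- (pattern-) selective if its partial correlation
  significantly exceeds both zero and the rival, else unclassed.
* **Opponency.**  12-dot kinematograms with 8 dots at a unit's
  preferred velocity and 4 at a distractor direction of equal speed;
  profiles are normalised to the coherent condition, symmetric offsets
  averaged, and each unit's maximal-suppression offset is the argmin of
  the folded profile.  The headline statistic is the Pearson
  correlation of that offset with preferred speed over the 64 MT units
  (and the analogous, weaker, V1 statistic over kernels probed at their
  preferred grating velocity).
* **Offset bias.**  MT offsets are averaged across directions within
  each preferred speed and correlated with speed (n = 8).  The V1
  statistic is a two-sample t between conv offsets of units whose
  largest-|weight| readout connection targets the four slowest vs the
  four fastest speed columns, restricted to the top half of units by
  that influence measure.
* **Image similarity.**  Pearson correlation between a texture
  translated at direction 0 and the same source translated at offsets
  up to 180 degrees, per speed; the near-preferred offsets
  (22.5/45/67.5 degrees) x 8 speeds (n = 24) are correlated with the
  max-normalised aligned MT tuning values at the same offsets.

## Prior models

Both models operate on a discretised speed axis (201 points on [0, 2])
with a population response r = p + A exp(-(x-x0)^2 / 2 sigma^2) and a
slow-speed gradient e(x) = max(0, 0.5 - 0.5 x).  The additive rule
normalises r + e, the multiplicative rule normalises r * e; decoded
speed is the peak of a Gaussian fit to the combined population.  The
additive decoded-peak shift scales with sigma^2/A, the multiplicative
shift with sigma^2 alone — scaling r leaves the multiplicative decode
unchanged while pushing the additive decode toward the bias, which is
the testable dissociation.

The two-interval matching experiment is simulated per trial as a noisy
observer: a sensory sample from the condition's Gaussian plus the
model's deterministic decoded-peak shift for that condition, compared
against a baseline sample treated the same way; the psychometric fit of
the resulting choice proportions gives threshold (PSE) and slope.
Sampling trial values directly from the normalised combined population
distributions was rejected: a wider Gaussian of equal amplitude carries
more probability mass, which dilutes the additive bias and shifts
truncated means, conflating amplitude with uncertainty and destroying
the dissociation the experiment is designed to expose.  Conditions:
baseline (x0 0.5, A 1, sigma 0.2), low contrast (A 0.05, sigma 0.5),
variable speed (A 1, sigma 0.5); 20 offsets in [-1, 1], 500 trials per
offset.

## Numerical choices

* Tie-breaks: classification argmax resolves to the lowest index;
  suppression-offset argmin likewise.
* Von Mises / Gaussian fits use bounded least squares with
  data-derived initialisation; psychometric fits use L-BFGS-B from
  several starts.  Degenerate inputs (flat responses, all-identical
  proportions) return flagged fallbacks rather than raising.
* The orientation-energy census whitens the spectrum radially (so the
  1/f slope and the coarse angular sampling of the lowest-frequency
  rings cannot bias it) and applies a Hann window (so the periodic-wrap
  discontinuity of non-periodic images cannot either).  Rasterised
  isotropic dot images still read slightly cardinal (~1.3); census
  comparisons are therefore made between conditions rather than
  against an absolute 1.
* All stochastic procedures take explicit seeds or Generators;
  training, corpus generation and simulations are bit-reproducible.

## Known limitations

* Grating generalisation at desk scale falls far short of a fully
  trained photographic network.  Clean, localised spatiotemporal
  filters require both sparse oriented image structure and on the
  order of 10^6 gradient updates; Gaussian-phase textures at ~10^3-10^4
  updates yield features that classify held-out textures well (the
  training loss saturates near zero) but transfer only partially to
  single sinusoids.  A dead-leaves texture model (occluding power-law
  ellipses, available as ``TextureConfig(model="dead_leaves")``)
  narrows but does not close this gap.
* The learned offset-speed correlation at desk scale is dominated by
  an early-training calibration gradient tied to class confusability
  rather than by the (weak, rho ~ 0.05 over the trained speed range)
  speed-contrast association of the corpus.  The standard network's
  strongly negative correlation and its modulation by blurring and
  sharpening reproduce at desk scale; the sign flip under the
  reverse-contrast manipulation does not — reversing the association
  softens the correlation without crossing zero, because the
  calibration component is untouched.  Observing the flip requires the
  association to dominate the offsets, i.e. full-scale convergence.
* The opponency-speed interrelation is directionally negative but
  statistically weak at desk scale (rho about -0.1 to -0.3 depending
  on dot placements); it is tested as a sign/ordering property.
* Decodes of very low-contrast thin rhombi leave the IOC-VA sector
  entirely; analyses flag the stable contrast regime.
* Pattern/component classification at desk scale yields more unclassed
  units than a converged network would.
* The psychometric sensitivity scale (1/sigma) is one of several
  defensible readings of "reciprocal of the just noticeable
  difference"; all preserve the cardinal > oblique ordering.
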