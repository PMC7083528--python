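# motionperc

Tools for studying how the statistics of static images shape motion
perception, built around a shallow convolutional velocity classifier.

A two-layer network — a bank of 3D spatiotemporal kernels ("V1") read
out by a 64-way softmax over an 8-direction x 8-speed grid ("MT") — is
trained to classify the velocity of rigidly translating image
sequences.  The package provides:

* **synthetic training worlds** with controlled image statistics:
  1/f^a-spectrum textures with a tunable cardinal:oblique
  orientation-energy ratio, random-dot worlds (optionally distorted
  onto cardinal or oblique axes), and corpus manipulations that reverse
  the speed-contrast association, blur/sharpen the images, or tilt the
  speed distribution ("slow world" / "fast world");
* **the network** itself (numpy implementation: valid convolution,
  half-wave rectification, stride-1 average pooling, softmax readout,
  plain constant-rate mini-batch SGD on the cross entropy);
* **a laboratory stimulus battery**: drifting gratings, plaids
  (speed-ratio, unikinetic and contrast-ratio series), barber poles,
  dot kinematograms with motion-opponent subsets, and moving rhombi;
* **decoders** that turn the discrete 64-unit response into continuous
  direction/speed estimates (von Mises / Gaussian population fits) and
  psychometric functions (cumulative Gaussian with lapse, JND = sigma,
  sensitivity = 1/JND);
* **neurophysiology-style analyses**: unit tuning maps and anisotropy
  censuses, pattern/component classification by partial correlation
  with Fisher-z significance, V1-to-MT readout-weight alignment, motion
  opponency, intersection-of-constraints (IOC) vs vector-average (VA)
  reference solutions, offset-parameter bias, inter-direction image
  similarity, and the speed/spatiotemporal-contrast association;
* **prior models**: the additive offset model vs a multiplicative
  slow-world prior, with a simulated two-interval speed-matching
  experiment that dissociates them.

## Worked example

```python
import numpy as np
from motionperc import corpus, network, analyses

# an autocorrelated, cardinally biased texture corpus: 64 velocity
# classes x 20 sequences, split 70/15/15
gen = corpus.texture_sequence_generator()
ts  = corpus.build_training_set(gen, n_per_class=20, seed=0)
print(round(corpus.corpus_speed_contrast_correlation(ts), 3))
# 0.036  -- faster sequences carry slightly higher spatiotemporal contrast

net = network.train_fresh(
    ts,
    network.scaled_architecture(16),
    network.scaled_training_config(epochs=100, seed=0),
)
print(net.log[-1])   # (99, 0.0154, 0.240): epoch, train loss, val accuracy
# (24% held-out accuracy vs 1.56% chance for this one-minute training)

bias = analyses.offset_bias_analysis(net)
print(round(bias["rho_mt"], 2))
# -0.59  -- offsets of slow-preferring MT units sit above fast-preferring ones
```

`offset_bias_analysis` correlates each MT unit's learned offset
parameter (averaged across directions) with its preferred speed: on an
autocorrelated corpus the correlation is negative — slow-preferring
units keep higher baseline excitability, which is what produces the
slower-at-low-contrast misperception.  Training on the
`reverse_speed_contrast` corpus weakens the correlation; flipping its
sign outright requires training regimes beyond desk scale (see
`docs/methods.md`, Known limitations).

Architecture accounting for the full-width reference network:

```python
>>> network.count_parameters()
{'conv_params': 27776, 'conv_connections': 20155392, 'units': 36992,
 'readout_weights': 2367488, 'readout_offsets': 64,
 'chance_percent': 1.5625}
```

A command-line interface mirrors the library
(`motionperc generate / train / analyze / simulate / reproduce`); see
`motionperc --help`.

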