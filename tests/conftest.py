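"""Shared fixtures.

The expensive trained networks are session-scoped and shared across the
acceptance tests; unit tests only use tiny architectures and corpora.
Three training tiers are used (see docs/methods.md): the standard
desk-scale network (32 kernels, 50 sequences/class, 200 epochs),
reduced-scale replicate/manipulation networks, and small census
networks for the anisotropy experiments.
"""

from __future__ import annotations

import numpy as np
import pytest

from motionperc import analyses as an
from motionperc import corpus as cp
from motionperc import network as nw


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_arch():
    return nw.Architecture(n_kernels=3, kernel_size=4, input_size=10, n_frames=3, pooling=True, pool_size=3)


@pytest.fixture
def tiny_net(tiny_arch):
    """Small random-parameter network for numeric checks (float64)."""
    net = nw.init_network(1, tiny_arch)
    r = np.random.default_rng(2)
    net.kernels = r.normal(0, 0.1, net.kernels.shape)
    net.conv_offsets = r.normal(0, 0.1, net.conv_offsets.shape)
    net.readout = r.normal(0, 0.1, net.readout.shape)
    net.readout_offsets = r.normal(0, 0.1, net.readout_offsets.shape)
    return net


@pytest.fixture(scope="session")
def small_texture_corpus():
    """Texture corpus small enough for unit tests (1,280 sequences)."""
    gen = cp.texture_sequence_generator()
    return cp.build_training_set(gen, n_per_class=20, seed=1)


# ---------------------------------------------------------------------------
# trained networks (shared by the acceptance tests)

STANDARD_SEED = 0
#: desk-scale study conditions: 32 kernels, 50 sequences/class, 200 epochs
STANDARD_KW = dict(n_kernels=32, n_per_class=50, epochs=200)
#: reduced conditions for corpus-manipulation and census replicates
VARIANT_KW = dict(n_kernels=16, n_per_class=16, epochs=80)
VARIANT_SEEDS = (11, 12, 13)
CENSUS_ANISOTROPY = 4.0
#: coarse SF/TF grid for direction censuses (full 8 x 8 grid elsewhere)
CENSUS_SF = 2.0 ** np.linspace(1, 6, 4)
CENSUS_TF = 2.0 ** np.linspace(1, 6, 4)


def train_on(ts, n_kernels, epochs, seed):
    cfg = nw.scaled_training_config(epochs=epochs, seed=seed)
    return nw.train_fresh(ts, nw.scaled_architecture(n_kernels), cfg)


@pytest.fixture(scope="session")
def standard_corpus():
    gen = cp.texture_sequence_generator()
    return cp.build_training_set(gen, n_per_class=STANDARD_KW["n_per_class"], seed=STANDARD_SEED)


@pytest.fixture(scope="session")
def standard_net(standard_corpus):
    """The scaled standard network: autocorrelated textures, uniform speeds."""
    return train_on(
        standard_corpus, STANDARD_KW["n_kernels"], STANDARD_KW["epochs"], STANDARD_SEED
    )


@pytest.fixture(scope="session")
def standard_tuning(standard_net):
    return an.map_unit_tuning(standard_net, n_phases=8)


@pytest.fixture(scope="session")
def replicate_corpora():
    gen = cp.texture_sequence_generator()
    return {
        seed: cp.build_training_set(gen, n_per_class=VARIANT_KW["n_per_class"], seed=seed)
        for seed in VARIANT_SEEDS
    }


@pytest.fixture(scope="session")
def replicate_nets(replicate_corpora):
    """Reduced-scale standard networks, one per replicate seed."""
    return [
        train_on(ts, VARIANT_KW["n_kernels"], VARIANT_KW["epochs"], seed)
        for seed, ts in replicate_corpora.items()
    ]


def _variant_train(ts, seed):
    return train_on(ts, VARIANT_KW["n_kernels"], VARIANT_KW["epochs"], seed)


@pytest.fixture(scope="session")
def variant_nets(replicate_corpora, replicate_nets):
    """Reduced-scale networks per corpus manipulation.

    standard / blur / sharpen on all replicate seeds; the speed-world
    and reverse manipulations on the first seed only.
    """
    nets: dict[tuple[str, int], nw.NetworkParams] = {}
    for seed, net in zip(VARIANT_SEEDS, replicate_nets):
        nets[("standard", seed)] = net
    for seed, ts in replicate_corpora.items():
        for mode in ("blur", "sharpen"):
            nets[(mode, seed)] = _variant_train(cp.blur_or_sharpen(ts, mode), seed)
    first = VARIANT_SEEDS[0]
    gen = cp.texture_sequence_generator()
    for world in ("slow", "fast"):
        ts = cp.build_training_set(
            gen, n_per_class=VARIANT_KW["n_per_class"], seed=first, speed_world=world
        )
        nets[(world, first)] = _variant_train(ts, first)
    nets[("reverse", first)] = _variant_train(
        cp.reverse_speed_contrast(replicate_corpora[first]), first
    )
    return nets


@pytest.fixture(scope="session")
def variant_rhos(variant_nets):
    """MT offset-vs-speed correlations per corpus manipulation."""
    rhos: dict[str, list[float]] = {}
    for (mode, _seed), net in variant_nets.items():
        rhos.setdefault(mode, []).append(an.offset_bias_analysis(net)["rho_mt"])
    return rhos


def _census_map(net):
    return an.map_unit_tuning(net, n_phases=8, sf_grid=CENSUS_SF, tf_periods=CENSUS_TF)


@pytest.fixture(scope="session")
def census_tunings(standard_net, variant_nets):
    """Direction-preference tables of replicate networks per training world.

    The cardinal census pools seven networks trained on cardinally
    anisotropic image statistics: the standard desk-scale network plus
    the reduced-scale standard and sharpened replicates (sharpening
    preserves the angular energy ratio; blurring does not).  The
    rotated-texture and isotropic-dot controls use three
    strong-anisotropy replicates each.
    """
    out: dict[str, list] = {"cardinal": [], "rotated": [], "dots": []}
    out["cardinal"].append(_census_map(standard_net))
    for (mode, seed), net in variant_nets.items():
        if mode in ("standard", "sharpen"):
            out["cardinal"].append(_census_map(net))
    rotated = cp.texture_sequence_generator(
        cp.TextureConfig(orientation_anisotropy=CENSUS_ANISOTROPY, anisotropy_axis_deg=45.0)
    )
    dots = cp.dot_sequence_generator()
    for kind, gen, seeds in (("rotated", rotated, (100, 101, 102)), ("dots", dots, (100, 101, 102))):
        for seed in seeds:
            ts = cp.build_training_set(gen, n_per_class=VARIANT_KW["n_per_class"], seed=seed)
            out[kind].append(_census_map(_variant_train(ts, seed)))
    return out
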