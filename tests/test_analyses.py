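import numpy as np
import pytest

from motionperc import analyses as an
from motionperc import corpus as cp
from motionperc import network as nw
from motionperc import stimuli as st
from motionperc.types import Velocity, circdiff


# ---------------------------------------------------------------------------
# partial correlations and pattern/component labels


def test_partial_correlation_reduces_when_predictions_uncorrelated(rng):
    # construct responses with known plain correlations
    n = 16
    base = rng.normal(size=n)
    r = an.partial_correlations(base, base, rng.normal(size=n))
    assert r[3] == pytest.approx(1.0, abs=0.05)  # R_p ~ r_p when r_c ~ 0


def test_partial_correlation_printed_example():
    # r_p = r_c = r_cp = 0.5 -> R = 0.25 / 0.75 = 1/3
    denom = np.sqrt((1 - 0.25) * (1 - 0.25))
    assert (0.5 - 0.25) / denom == pytest.approx(1 / 3)
    label, zp, zc = an._pattern_component_label(1 / 3, 1 / 3, 16)
    assert label == "unclassed"


def test_labels_follow_significance_rules():
    n = 16
    # strong pattern partial correlation, no component correlation
    label, _, _ = an._pattern_component_label(0.9, 0.0, n)
    assert label == "pattern"
    label, _, _ = an._pattern_component_label(0.0, 0.9, n)
    assert label == "component"
    label, _, _ = an._pattern_component_label(0.2, 0.1, n)
    assert label == "unclassed"


def test_labels_invariant_to_response_scaling(rng):
    grating = rng.uniform(0.1, 1.0, 16)
    plaid = np.roll(grating, 2) + np.roll(grating, -2)
    a = an._classify_from_curves(grating, plaid, 90.0, 0, "MT")
    b = an._classify_from_curves(grating * 7.5, plaid * 7.5, 90.0, 0, "MT")
    assert a.label == b.label
    assert a.R_p == pytest.approx(b.R_p, abs=1e-9)


def test_component_prediction_from_shifted_tuning(rng):
    # a unit whose plaid response is the sum of component-shifted tunings
    # must classify as component-selective
    dirs = np.arange(16) * 22.5
    grating = 0.1 + np.exp(3.0 * (np.cos(np.deg2rad(dirs)) - 1.0))
    plaid = 0.5 * (np.roll(grating, 2) + np.roll(grating, -2))
    res = an._classify_from_curves(grating, plaid, 90.0, 0, "MT")
    assert res.label == "component"
    # a unit whose plaid tuning equals its grating tuning is pattern-like
    res = an._classify_from_curves(grating, grating + rng.normal(0, 0.01, 16), 90.0, 0, "MT")
    assert res.label == "pattern"


def test_zero_variance_response_unclassed():
    res = an._classify_from_curves(np.ones(16), np.ones(16), 90.0, 0, "MT")
    assert res.label == "unclassed"


# ---------------------------------------------------------------------------
# IOC and vector average


def test_ioc_printed_example():
    ioc = an.ioc_velocity(Velocity(45.0, 1.0), Velocity(315.0, 1.0))
    assert ioc.speed == pytest.approx(np.sqrt(2.0), abs=1e-4)
    assert ioc.direction == pytest.approx(0.0, abs=1e-6)
    va = an.va_velocity(Velocity(45.0, 1.0), Velocity(315.0, 1.0))
    assert va.speed == pytest.approx(np.sqrt(2.0) / 2.0, abs=1e-4)
    assert va.direction == pytest.approx(0.0, abs=1e-6)


def test_ioc_identical_and_parallel_components():
    ioc = an.ioc_velocity(Velocity(30.0, 1.5), Velocity(30.0, 1.5))
    assert (ioc.direction, ioc.speed) == (30.0, 1.5)  # coincident constraints
    # genuinely parallel but inconsistent constraints have no solution
    with pytest.raises(np.linalg.LinAlgError):
        an.ioc_velocity(Velocity(30.0, 1.5), Velocity(210.0, 1.0))
    near = an.ioc_velocity(Velocity(30.0, 1.5), Velocity(31.0, 1.5))
    assert near.speed == pytest.approx(1.5, rel=0.01)


def test_unikinetic_ioc_parallel_to_static_orientation():
    # static component: constraint line through the origin; the IOC moves
    # along the static grating's orientation (orthogonal to its drift axis)
    static = Velocity(90.0, 0.0)
    moving = Velocity(45.0, 2.0)
    ioc = an.ioc_velocity(static, moving)
    # velocity component along the static drift axis is zero
    assert ioc.cartesian[1] == pytest.approx(0.0, abs=1e-9)


def test_ioc_matches_brute_force_constraint_search(rng):
    """Grid search over velocity space agrees with the closed-form solve."""
    for _ in range(50):
        d1, d2 = rng.uniform(0, 360, 2)
        sep = abs(circdiff(d1, d2)) % 180.0
        if sep < 30.0 or sep > 150.0:
            continue  # near-parallel constraints give solutions off the grid
        s1, s2 = rng.uniform(0.5, 3.5, 2)
        c1, c2 = Velocity(d1, s1), Velocity(d2, s2)
        ioc = an.ioc_velocity(c1, c2)
        # brute force: minimise constraint violation on a grid
        vx = np.linspace(-16, 16, 641)
        VX, VY = np.meshgrid(vx, vx)
        th1, th2 = np.deg2rad(d1), np.deg2rad(d2)
        err = (VX * np.cos(th1) + VY * np.sin(th1) - s1) ** 2 + (
            VX * np.cos(th2) + VY * np.sin(th2) - s2
        ) ** 2
        i, j = np.unravel_index(np.argmin(err), err.shape)
        assert VX[i, j] == pytest.approx(ioc.cartesian[0], abs=0.06)
        assert VY[i, j] == pytest.approx(ioc.cartesian[1], abs=0.06)


def test_rhombus_components_intersect_at_true_velocity():
    spec = st.RhombusSpec(aspect_ratio=0.1)
    c1, c2 = an.rhombus_components(spec)
    ioc = an.ioc_velocity(c1, c2)
    assert ioc.direction == pytest.approx(spec.direction, abs=1e-6)
    assert ioc.speed == pytest.approx(spec.speed, rel=1e-6)
    va = an.va_velocity(c1, c2)
    # thin rhombus: the vector average points well away from the truth
    assert abs(circdiff(va.direction, spec.direction)) > 20.0


# ---------------------------------------------------------------------------
# image statistics


def test_similarity_is_one_at_zero_offset(rng):
    df = an.image_similarity_analysis(n_sources=4, rng=rng)
    zero = df[df["offset"] == 0.0]["similarity"]
    assert np.allclose(zero, 1.0, atol=1e-6)


def test_similarity_decreases_with_speed_at_fixed_offset(rng):
    df = an.image_similarity_analysis(n_sources=30, rng=rng)
    sub = df[df["offset"] == 90.0].sort_values("speed")["similarity"].to_numpy()
    assert sub[-1] < sub[0]


def test_white_noise_similarity_sits_at_shared_frame_floor(rng):
    """Sequences at different directions share frame 0 exactly, so the
    pooled correlation cannot drop below ~1/6; white noise reaches that
    floor at fast speeds and large offsets, autocorrelated textures stay
    far above it."""
    white = cp.TextureConfig(model="spectral", spectral_exponent=0.0, orientation_anisotropy=1.0)
    dfw = an.image_similarity_analysis(white, rng=rng, n_sources=12)
    dfa = an.image_similarity_analysis(n_sources=12, rng=np.random.default_rng(5))
    far_w = dfw[(dfw["offset"] >= 90.0) & (dfw["speed"] > 2.0)]["similarity"]
    far_a = dfa[(dfa["offset"] >= 90.0) & (dfa["speed"] > 2.0)]["similarity"]
    assert far_w.max() < 0.35
    assert far_a.min() > far_w.max()


def test_spatiotemporal_contrast_examples():
    assert cp.spatiotemporal_contrast(np.zeros((4, 4, 6))) == 0.0
    two_valued = np.ones((4, 4, 6), dtype=np.float32)
    two_valued[:2] = -1.0
    assert cp.spatiotemporal_contrast(two_valued) == pytest.approx(1.0)


def test_speed_contrast_correlation_positive_on_textures(rng):
    rho, p = an.speed_contrast_correlation(n=150, rng=rng)
    assert rho > 0.1 and p < 0.05


# ---------------------------------------------------------------------------
# alignment and opponency machinery (no trained net required)


def test_alignment_by_max_weight_peaks_at_zero(rng):
    arch = nw.scaled_architecture(8)
    net = nw.init_network(0, arch)
    net.readout = rng.normal(size=net.readout.shape).astype(np.float32)
    prof = an.align_readout_weights(net, "by_max_weight")
    peak_offset = prof.loc[prof["weight"].idxmax(), "offset"]
    assert peak_offset == 0.0


def test_cosine_tuned_unit_max_suppressed_opposite():
    # folding and argmin machinery on an analytic cosine tuning profile
    prof8 = 1.0 + np.cos(np.deg2rad(np.arange(8) * 45.0))
    folded = np.array([prof8[0], (prof8[1] + prof8[7]) / 2, (prof8[2] + prof8[6]) / 2,
                       (prof8[3] + prof8[5]) / 2, prof8[4]])
    offsets = np.array([0.0, 45.0, 90.0, 135.0, 180.0])
    assert offsets[int(np.argmin(folded))] == 180.0
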