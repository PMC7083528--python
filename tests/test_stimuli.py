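import numpy as np
import pytest

from motionperc import stimuli as st
from motionperc.types import Velocity


# ---------------------------------------------------------------------------
# gratings


def test_full_contrast_grating_spans_unit_range():
    g = st.make_grating(st.GratingSpec(contrast=1.0))
    assert g.pixels.min() == pytest.approx(-1.0, abs=0.01)
    assert g.pixels.max() == pytest.approx(1.0, abs=0.01)


def test_zero_contrast_grating_is_uniform():
    g = st.make_grating(st.GratingSpec(contrast=0.0))
    assert np.allclose(g.pixels, 0.0)


def test_opposite_phases_negate():
    a = st.make_grating(st.GratingSpec(phase=0.0))
    b = st.make_grating(st.GratingSpec(phase=180.0))
    assert np.allclose(a.pixels, -b.pixels, atol=1e-6)


def test_temporal_frequency_implies_speed():
    spec = st.GratingSpec(spatial_frequency=16.0, temporal_frequency=0.1)
    assert spec.speed_px == pytest.approx(1.6)
    with pytest.raises(ValueError):
        st.GratingSpec(spatial_frequency=16.0, temporal_frequency=0.1, speed=3.0)


def test_grating_drifts_at_stated_speed():
    # one frame at speed v shifts the sinusoid by v pixels along the drift axis
    spec = st.GratingSpec(direction=0.0, speed=2.0)
    g = st.make_grating(spec).pixels
    rolled = np.roll(g[:, :, 0], 2, axis=1)
    assert np.allclose(g[:, :, 1], rolled, atol=1e-5)


@pytest.mark.parametrize("maker,kw", [
    (st.make_grating, dict(contrast=0.5)),
    (st.make_rhombus, dict(contrast=0.5)),
])
def test_contrast_roundtrip(maker, kw):
    spec = st.GratingSpec(**kw) if maker is st.make_grating else st.RhombusSpec(aspect_ratio=0.8, **kw)
    seq = maker(spec)
    assert st.measure_contrast(seq) == pytest.approx(kw["contrast"], abs=0.02)


def test_measure_contrast_examples():
    assert st.measure_contrast(np.zeros((4, 4, 2))) == 0.0
    assert st.measure_contrast(np.array([[[-0.5, 0.5]]])) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        st.measure_contrast(np.zeros((0, 0, 0)))


def test_rotating_spec_matches_rotating_frames():
    # 90 deg rotation of the generated frames equals generating at +90 deg,
    # up to a start phase (the rotation centre is not the phase origin)
    a = st.make_grating(st.GratingSpec(direction=0.0, speed=1.6, phase=30.0)).pixels
    rotated = np.stack([np.rot90(a[:, :, k]) for k in range(a.shape[2])], axis=2)
    best = max(
        np.corrcoef(
            rotated.ravel(),
            st.make_grating(st.GratingSpec(direction=90.0, speed=1.6, phase=ph)).pixels.ravel(),
        )[0, 1]
        for ph in np.arange(0.0, 360.0, 7.5)
    )
    assert best > 0.995


# ---------------------------------------------------------------------------
# plaids


def test_plaid_is_sum_of_components_when_unclipped():
    spec = st.PlaidSpec(contrasts=(0.3, 0.3))
    plaid = st.make_plaid(spec)
    c1, c2 = spec.component_specs()
    total = st.make_grating(c1).pixels + st.make_grating(c2).pixels
    assert np.allclose(plaid.pixels, total, atol=1e-6)


def test_symmetric_plaid_is_mirror_symmetric_about_pattern_axis():
    spec = st.PlaidSpec(direction=0.0, separation=90.0, speeds=(0.8, 0.8), contrasts=(0.4, 0.4))
    plaid = st.make_plaid(spec).pixels
    # the amplitude spectrum (phase-free) is symmetric under a vertical
    # flip: the two components mirror onto each other about the pattern axis
    for k in range(plaid.shape[2]):
        amp = np.abs(np.fft.fftshift(np.fft.fft2(plaid[:, :, k])))
        flipped = amp[::-1, :]
        flipped = np.roll(flipped, 1, axis=0)  # even-size fftshift alignment
        assert np.allclose(amp, flipped, atol=1e-3 * amp.max())


def test_contrast_ratio_arithmetic():
    specs = st.contrast_ratio_series(total_contrasts=(0.04,), n_steps=8)
    first = specs[0]
    assert first.contrasts[0] == pytest.approx(0.02)
    assert first.contrasts[1] == pytest.approx(0.02)
    for s in specs:
        assert sum(s.contrasts) == pytest.approx(0.04)


def test_zero_total_contrast_rejected():
    with pytest.raises(ValueError):
        st.PlaidSpec(contrasts=(0.0, 0.0))


def test_unikinetic_degenerate_flag():
    seq = st.unikinetic_plaid(0.0)
    assert seq.meta["degenerate"]
    seq = st.unikinetic_plaid(30.0)
    assert not seq.meta["degenerate"]


# ---------------------------------------------------------------------------
# barber poles


@pytest.mark.parametrize("ratio", list(range(1, 17)))
def test_barber_pole_exact_aspect_ratio(ratio):
    seq = st.make_barber_pole(st.BarberPoleSpec(aspect_ratio=ratio))
    h, w = seq.meta["aperture"]
    assert h == ratio * w
    # area maximal among exact integer solutions
    best = max(w2 * ratio * w2 for w2 in range(1, 33) if ratio * w2 <= 32)
    assert h * w == best


def test_barber_pole_masked_area_complementary():
    seq = st.make_barber_pole(st.BarberPoleSpec(aspect_ratio=16))
    h, w = seq.meta["aperture"]
    masked = np.sum(np.all(seq.pixels == 0.0, axis=2))
    assert w == 2 and h == 32
    assert masked + h * w >= 32 * 32  # grating zero-crossings can add to the count


# ---------------------------------------------------------------------------
# dot stimuli


def test_opponent_split_is_8_vs_4(rng):
    spec = st.DotMotionSpec(coherent_fraction=0.66, distractor_direction=180.0)
    n_probe = int(round(spec.coherent_fraction * spec.n_dots))
    assert n_probe == 8 and spec.n_dots - n_probe == 4


def test_coherent_dots_all_move_together(rng):
    spec = st.DotMotionSpec()
    seq = st.make_dot_stimulus(spec, Velocity(0.0, 2.0), rng)
    # rigid translation with wraparound: frame k+1 equals frame k rolled 2 px
    assert np.allclose(seq.pixels[:, :, 1], np.roll(seq.pixels[:, :, 0], 2, axis=1), atol=0.15)


def test_dot_wraparound_conserves_mass(rng):
    spec = st.DotMotionSpec(n_dots=1)
    seq = st.make_dot_stimulus(spec, Velocity(0.0, 3.8), rng)
    mass = (seq.pixels + 1.0).sum(axis=(0, 1))
    assert np.allclose(mass, mass[0], rtol=0.02)


def test_distractor_required_for_incoherent(rng):
    with pytest.raises(ValueError):
        st.make_dot_stimulus(
            st.DotMotionSpec(coherent_fraction=0.66), Velocity(0.0, 1.0), rng
        )


# ---------------------------------------------------------------------------
# rhombi


def test_rhombus_geometry():
    spec = st.RhombusSpec(aspect_ratio=0.1)
    assert spec.width == pytest.approx(1.6)
    seq = st.make_rhombus(spec)
    assert seq.pixels.max() == pytest.approx(1.0, abs=0.05)
    assert seq.pixels.min() == -1.0


def test_static_rhombus():
    spec = st.RhombusSpec(speed=0.0, aspect_ratio=0.8)
    seq = st.make_rhombus(spec)
    for k in range(1, seq.n_frames):
        assert np.allclose(seq.pixels[:, :, k], seq.pixels[:, :, 0])


def test_rhombus_translates_rigidly():
    spec = st.RhombusSpec(aspect_ratio=0.8, speed=2.0, contrast=1.0)
    seq = st.make_rhombus(spec).pixels
    # centroid of the bright mass moves 2 px rightward per frame
    cols = np.arange(32)
    mass = seq + 1.0
    cx = [(mass[:, :, k] * cols[None, :]).sum() / mass[:, :, k].sum() for k in range(6)]
    steps = np.diff(cx)
    assert np.allclose(steps, 2.0, atol=0.05)


def test_rhombus_requires_positive_contrast():
    with pytest.raises(ValueError):
        st.RhombusSpec(contrast=0.0)


def test_save_frames_roundtrip(tmp_path):
    import json

    import tifffile

    spec = st.GratingSpec(direction=45.0, speed=1.6, contrast=0.8)
    seq = st.make_grating(spec)
    path = tmp_path / "grating.tiff"
    st.save_frames(seq, path, spec)
    frames = tifffile.imread(path)
    assert frames.shape == (6, 32, 32)
    back = frames.astype(np.float64) / 65535.0 * 2.0 - 1.0
    assert np.allclose(np.moveaxis(back, 0, 2), seq.pixels, atol=1e-3)
    meta = json.loads(path.with_suffix(".json").read_text())
    assert meta["spec"]["direction"] == 45.0
    assert meta["velocity"]["speed"] == pytest.approx(1.6)
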