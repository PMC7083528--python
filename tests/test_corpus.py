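import warnings

import numpy as np
import pytest

from motionperc import corpus as cp
from motionperc.types import Velocity


# ---------------------------------------------------------------------------
# textures


def test_white_noise_has_no_lag1_autocorrelation(rng):
    cfg = cp.TextureConfig(model="spectral", spectral_exponent=0.0, orientation_anisotropy=1.0)
    acs = [cp.lag1_autocorrelation(cp.generate_texture(cfg, rng).pixels) for _ in range(40)]
    assert abs(np.mean(acs)) < 0.05


def test_pink_noise_is_strongly_autocorrelated(rng):
    # frozen regression bound: 1/f textures average lag-1 correlation ~0.7
    cfg = cp.TextureConfig(model="spectral", spectral_exponent=1.0, orientation_anisotropy=1.0)
    acs = [cp.lag1_autocorrelation(cp.generate_texture(cfg, rng).pixels) for _ in range(100)]
    assert np.mean(acs) > 0.5


def test_orientation_energy_tracks_anisotropy(rng):
    wins = 0
    cfg = cp.TextureConfig(orientation_anisotropy=4.0)
    for _ in range(100):
        wins += cp.orientation_energy_ratio(cp.generate_texture(cfg, rng).pixels) > 1.0
    assert wins >= 95
    iso = cp.TextureConfig(orientation_anisotropy=1.0)
    ratios = [cp.orientation_energy_ratio(cp.generate_texture(iso, rng).pixels) for _ in range(60)]
    assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)


def test_rotated_anisotropy_axis_flips_census(rng):
    cfg = cp.TextureConfig(orientation_anisotropy=4.0, anisotropy_axis_deg=45.0)
    ratios = [cp.orientation_energy_ratio(cp.generate_texture(cfg, rng).pixels) for _ in range(60)]
    assert np.mean(ratios) < 1.0


def test_texture_intensities_in_unit_range(rng):
    tex = cp.generate_texture(cp.TextureConfig(), rng)
    assert tex.pixels.min() >= -1.0 and tex.pixels.max() <= 1.0


def test_source_size_must_fit_patch_plus_travel():
    with pytest.raises(ValueError):
        cp.TextureConfig(source_size=40)


# ---------------------------------------------------------------------------
# translation


def _impulse_source(size=64):
    src = np.zeros((size, size), dtype=np.float32)
    src[size // 2, size // 2] = 1.0
    return src


@pytest.mark.parametrize(
    "direction,expected_dxy",
    [(0.0, (1.0, 0.0)), (45.0, (0.7071, 0.7071))],
)
def test_per_frame_displacement(direction, expected_dxy, rng):
    """Content moving at speed 1 displaces by (cos, sin) per frame."""
    src = cp.generate_texture(cp.TextureConfig(), rng).pixels[:, :, 0]
    seq = cp.translate_sequence(src, Velocity(direction, 1.0))
    # recover the displacement between consecutive frames by cross-correlation
    f0 = np.fft.fft2(seq.pixels[2:-2, 2:-2, 0])
    f1 = np.fft.fft2(seq.pixels[2:-2, 2:-2, 3])
    cross = np.fft.ifft2(f1 * np.conj(f0))
    peak = np.unravel_index(np.argmax(np.abs(cross)), cross.shape)
    n = cross.shape[0]
    drow = ((peak[0] + n / 2) % n) - n / 2
    dcol = ((peak[1] + n / 2) % n) - n / 2
    dx_exp, dy_exp = expected_dxy
    assert dcol == pytest.approx(3 * dx_exp, abs=0.5)
    assert -drow == pytest.approx(3 * dy_exp, abs=0.5)


def test_zero_speed_gives_identical_frames(rng):
    src = cp.generate_texture(cp.TextureConfig(), rng).pixels[:, :, 0]
    seq = cp.translate_sequence(src, Velocity(0.0, 0.0))
    for k in range(1, seq.n_frames):
        assert np.allclose(seq.pixels[:, :, k], seq.pixels[:, :, 0])


def test_window_leaving_source_raises(rng):
    src = np.zeros((56, 56), dtype=np.float32)
    with pytest.raises(ValueError):
        cp.translate_sequence(src, Velocity(0.0, 3.8), origin=(10.0, 40.0))


def test_fourier_and_bilinear_agree_on_smooth_source(rng):
    cfg = cp.TextureConfig(model="spectral", spectral_exponent=1.5, orientation_anisotropy=1.0)
    src = cp.generate_texture(cfg, rng).pixels[:, :, 0]
    a = cp.translate_sequence(src, Velocity(45.0, 1.0), origin=(14.0, 14.0), method="bilinear")
    b = cp.translate_sequence(src, Velocity(45.0, 1.0), origin=(14.0, 14.0), method="fourier")
    # integer-pixel frame 0 matches exactly; subpixel frames agree closely
    assert np.allclose(a.pixels[:, :, 0], b.pixels[:, :, 0], atol=1e-5)
    assert np.corrcoef(a.pixels[:, :, 3].ravel(), b.pixels[:, :, 3].ravel())[0, 1] > 0.98


# ---------------------------------------------------------------------------
# dot worlds


def test_static_dot_world_frames_identical(rng):
    cfg = cp.DotWorldConfig(n_dots=(1, 1))
    seq = cp.make_dot_sequence(cfg, Velocity(0.0, 0.0), rng)
    for k in range(1, seq.n_frames):
        assert np.array_equal(seq.pixels[:, :, k], seq.pixels[:, :, 0])


def test_dot_world_censuses(rng):
    def census(cfg, n=120):
        vals = []
        for _ in range(n):
            v = Velocity(rng.uniform(0, 360), rng.uniform(0.8, 3.8))
            seq = cp.make_dot_sequence(cfg, v, rng)
            if np.std(seq.pixels[:, :, 0]) > 1e-3:
                vals.append(cp.orientation_energy_ratio(seq.pixels[:, :, 0]))
        return np.mean(vals)

    iso = census(cp.DotWorldConfig())
    card = census(cp.DotWorldConfig(distortion_axis="cardinal"))
    obl = census(cp.DotWorldConfig(distortion_axis="oblique"))
    assert card > 2.0
    assert obl < 0.7
    assert obl < iso < card


def test_invalid_dot_config_rejected():
    with pytest.raises(ValueError):
        cp.DotWorldConfig(n_dots=(0, 5))
    with pytest.raises(ValueError):
        cp.DotWorldConfig(diameter=(-1.0, 4.0))


# ---------------------------------------------------------------------------
# training sets


def test_split_counts_at_full_corpus_size(rng):
    split = cp._split_assignment(64000, rng)
    assert int(np.sum(split == cp.TrainingSet.TRAIN)) == 44800
    assert int(np.sum(split == cp.TrainingSet.VAL)) == 9600
    assert int(np.sum(split == cp.TrainingSet.TEST)) == 9600


def test_small_corpus_split_and_balance(small_texture_corpus):
    ts = small_texture_corpus
    assert ts.n_train == 896  # 0.7 * 1280
    assert len(ts.y) == 1280
    counts = np.bincount(ts.y, minlength=64)
    assert np.all(counts == 20)
    # splits are disjoint and cover everything
    assert ts.X.min() >= -1.0 and ts.X.max() <= 1.0


def test_corpus_deterministic_under_seed():
    gen = cp.texture_sequence_generator()
    a = cp.build_training_set(gen, n_per_class=2, seed=7)
    b = cp.build_training_set(gen, n_per_class=2, seed=7)
    assert np.array_equal(a.X, b.X)
    assert np.array_equal(a.split, b.split)


def test_speed_world_counts():
    slow = cp._class_counts(10, "slow")
    fast = cp._class_counts(10, "fast")
    none = cp._class_counts(10, "none")
    assert np.all(none == 10)
    # slowest class holds twice the fastest (speed rank is index % 8)
    assert slow[0] == 20 and slow[7] == 10
    assert fast[0] == 10 and fast[7] == 20
    # mirrored under speed-rank reversal and balanced across directions
    assert np.array_equal(slow.reshape(8, 8), slow.reshape(8, 8)[0][None, :].repeat(8, 0))
    assert np.array_equal(slow.reshape(8, 8)[0], fast.reshape(8, 8)[0][::-1])


def test_speed_contrast_association_positive_and_reversible(small_texture_corpus):
    rho = cp.corpus_speed_contrast_correlation(small_texture_corpus)
    assert rho > 0.03
    rev = cp.reverse_speed_contrast(small_texture_corpus)
    assert cp.corpus_speed_contrast_correlation(rev) < 0.0
    # labels and splits untouched
    assert np.array_equal(rev.y, small_texture_corpus.y)
    assert np.array_equal(rev.split, small_texture_corpus.split)


def test_white_noise_corpus_has_no_association():
    gen = cp.texture_sequence_generator(
        cp.TextureConfig(model="spectral", spectral_exponent=0.0, orientation_anisotropy=1.0)
    )
    ts = cp.build_training_set(gen, n_per_class=15, seed=3)
    assert abs(cp.corpus_speed_contrast_correlation(ts)) < 0.07


def test_constant_sequences_left_unchanged_by_reverse():
    X = np.zeros((64, 32, 32, 6), dtype=np.float32)
    X[::2] += np.linspace(-0.5, 0.5, 32)[None, :, None, None]  # some contrast
    y = np.arange(64, dtype=np.int64)
    ts = cp.TrainingSet(X, y, np.zeros(64, dtype=np.int8), 0)
    with warnings.catch_warnings(record=True) as w:
        warnings.simplefilter("always")
        rev = cp.reverse_speed_contrast(ts)
    assert any("zero-contrast" in str(x.message) for x in w)
    assert np.array_equal(rev.X[1], X[1])  # flat sequence untouched


def test_blur_raises_and_sharpen_lowers_autocorrelation(small_texture_corpus):
    base = cp.corpus_lag1_autocorrelation(small_texture_corpus, 80)
    blurred = cp.blur_or_sharpen(small_texture_corpus, "blur")
    sharpened = cp.blur_or_sharpen(small_texture_corpus, "sharpen")
    assert cp.corpus_lag1_autocorrelation(blurred, 80) > base
    assert cp.corpus_lag1_autocorrelation(sharpened, 80) < base


def test_blur_sigma_zero_is_identity(small_texture_corpus):
    out = cp.blur_or_sharpen(small_texture_corpus, "blur", sigma=0.0)
    assert np.array_equal(out.X, small_texture_corpus.X)


def test_save_load_roundtrip(tmp_path, small_texture_corpus):
    path = tmp_path / "corpus.npz"
    small_texture_corpus.save(path)
    loaded = cp.TrainingSet.load(path)
    assert np.array_equal(loaded.X, small_texture_corpus.X)
    assert np.array_equal(loaded.y, small_texture_corpus.y)
    assert loaded.seed == small_texture_corpus.seed


def test_load_image_source_luminance_and_scaling(tmp_path, rng):
    import imageio.v3 as iio

    rgb = rng.integers(0, 255, size=(60, 60, 3), dtype=np.uint8)
    path = tmp_path / "photo.png"
    iio.imwrite(path, rgb)
    src = cp.load_image_source(path, contrast=0.3)
    assert src.pixels.shape == (60, 60, 1)
    assert abs(float(src.pixels.mean())) < 0.01
    assert float(src.pixels.std()) == pytest.approx(0.3, abs=0.02)
    # usable as a translation source
    seq = cp.translate_sequence(src, Velocity(0.0, 1.0))
    assert seq.shape == (32, 32, 6)
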