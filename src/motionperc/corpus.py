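"""Synthetic training corpora with controlled image statistics.

The velocity classifier is trained on short sequences made by rigidly
translating a source image behind a 32 x 32 window.  The statistical
properties that matter for everything downstream are (i) spatial
autocorrelation (a 1/f^a amplitude spectrum), which couples translation
speed to spatiotemporal contrast, and (ii) an excess of cardinal
orientation energy, which drives the cardinal direction anisotropy.  The
texture generator exposes both as dials; dot worlds provide an
orientation-free control with optional cardinal/oblique distortion.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Literal

import numpy as np
from scipy import ndimage

from .types import (
    N_FRAMES,
    PATCH_SIZE,
    TRAINED_DIRECTIONS,
    TRAINED_SPEEDS,
    ImageSequence,
    Velocity,
    class_index,
    class_velocity,
    rescale_to_unit,
    velocity_to_screen,
)

MAX_TRAVERSAL = N_FRAMES * TRAINED_SPEEDS[-1]  # 22.8 px over a sequence

SequenceGenerator = Callable[[np.random.Generator, Velocity], ImageSequence]


# ---------------------------------------------------------------------------
# textures


@dataclass(frozen=True)
class TextureConfig:
    """Synthetic texture parameters.

    Two texture models are available.  ``dead_leaves`` (the default)
    drops occluding elliptical "leaves" with a power-law size
    distribution — the standard synthetic model of natural scenes: it
    yields strong spatial autocorrelation, sharp occlusion edges (hence
    sparse oriented structure and a robust speed to spatiotemporal
    contrast association) and an approximately 1/f amplitude spectrum.
    ``spectral`` shapes Gaussian noise to a 1/f^a amplitude spectrum
    (phase-random: autocorrelated but edge-free; exponent 0 gives white
    noise).

    ``orientation_anisotropy`` is the cardinal:oblique orientation-energy
    ratio (1 = isotropic), implemented as an angular energy multiplier
    for the spectral model and as leaf elongation onto the cardinal axes
    for dead leaves; ``anisotropy_axis_deg`` rotates the favoured axes
    (45 swaps the excess onto the obliques).
    """

    source_size: int = 64
    model: Literal["spectral", "dead_leaves"] = "spectral"
    spectral_exponent: float = 1.0
    orientation_anisotropy: float = 2.0
    anisotropy_axis_deg: float = 0.0
    #: dead-leaves radius range (px) and power-law exponent of p(r)
    leaf_radius: tuple[float, float] = (2.0, 24.0)
    leaf_exponent: float = 3.0
    #: per-source RMS contrast range; the source is scaled to an RMS drawn
    #: uniformly from this interval and clipped to [-1, 1].  The default
    #: pins source contrast so that sequence-contrast variation reflects
    #: content and motion rather than source diversity
    contrast_range: tuple[float, float] = (0.3, 0.3)

    def __post_init__(self) -> None:
        min_size = PATCH_SIZE + int(np.ceil(MAX_TRAVERSAL))
        if self.source_size < min_size:
            raise ValueError(
                f"source_size {self.source_size} too small: need >= {min_size} "
                f"to fit a {PATCH_SIZE} px patch plus {MAX_TRAVERSAL:.1f} px of travel"
            )
        if self.orientation_anisotropy <= 0:
            raise ValueError("orientation_anisotropy must be positive")


def _spectral_filter(cfg: TextureConfig) -> np.ndarray:
    n = cfg.source_size
    fx = np.fft.fftfreq(n)[None, :]
    fy = np.fft.fftfreq(n)[:, None]
    rho = np.hypot(fx, fy)
    with np.errstate(divide="ignore"):
        amp = np.where(rho > 0, rho ** -cfg.spectral_exponent, 0.0)
    phi = np.arctan2(fy, fx) - np.deg2rad(cfg.anisotropy_axis_deg)
    # energy multiplier 1 + (a-1) cos^2(2 phi): ratio a on-axis vs off-axis
    energy = 1.0 + (cfg.orientation_anisotropy - 1.0) * np.cos(2.0 * phi) ** 2
    return amp * np.sqrt(energy)


def _dead_leaves_field(cfg: TextureConfig, rng: np.random.Generator) -> np.ndarray:
    """Occluding elliptical leaves with a power-law size distribution."""
    n = cfg.source_size
    canvas = np.full((n, n), rng.uniform(-1.0, 1.0))
    covered = np.zeros((n, n), dtype=bool)
    r_lo, r_hi = cfg.leaf_radius
    # inverse-CDF sampling of p(r) ~ r^-leaf_exponent on [r_lo, r_hi]
    a = 1.0 - cfg.leaf_exponent
    stretch = np.sqrt(np.sqrt(cfg.orientation_anisotropy))  # calibrated by census
    for _ in range(400):
        u = rng.uniform()
        r = (r_lo**a + u * (r_hi**a - r_lo**a)) ** (1.0 / a)
        cy, cx = rng.uniform(-r, n + r, 2)
        value = rng.uniform(-1.0, 1.0)
        if cfg.orientation_anisotropy == 1.0:
            ry = rx = r
            angle = 0.0
        else:
            ry, rx = r * stretch, r / stretch
            angle = rng.choice([0.0, 90.0]) + cfg.anisotropy_axis_deg
        _draw_ellipse(canvas, cy, cx, ry, rx, angle, value)
        yy, xx = np.ogrid[:n, :n]
        th = np.deg2rad(angle)
        u1 = (xx - cx) * np.cos(th) + (yy - cy) * np.sin(th)
        u2 = -(xx - cx) * np.sin(th) + (yy - cy) * np.cos(th)
        covered |= np.hypot(u1 / rx, u2 / ry) <= 1.0
        if covered.all():
            break
    return canvas


def generate_texture(cfg: TextureConfig, rng: np.random.Generator) -> ImageSequence:
    """Draw one texture source, scaled to the target RMS and clipped."""
    if cfg.model == "dead_leaves":
        shaped = _dead_leaves_field(cfg, rng)
    elif cfg.model == "spectral":
        noise = rng.standard_normal((cfg.source_size, cfg.source_size))
        shaped = np.real(np.fft.ifft2(np.fft.fft2(noise) * _spectral_filter(cfg)))
    else:
        raise ValueError(f"unknown texture model {cfg.model!r}")
    shaped = shaped - shaped.mean()
    sd = shaped.std()
    target = rng.uniform(*cfg.contrast_range)
    if sd > 0:
        shaped = np.clip(shaped * (target / sd), -1.0, 1.0)
    return ImageSequence(shaped[:, :, None], meta={"texture": asdict(cfg)})


def load_image_source(path: str | Path, contrast: float | None = 0.3) -> ImageSequence:
    """Load a PNG/TIFF image as a translation source (optional photo mode).

    RGB images are converted by the standard luminance transform; the
    result is zero-meaned and either scaled to the given RMS ``contrast``
    (clipped to [-1, 1]) or, with ``contrast=None``, scaled by its peak.
    """
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path), dtype=np.float64)
    if img.ndim == 3:
        img = img[..., :3] @ np.array([0.2126, 0.7152, 0.0722])
    img = img - img.mean()
    if contrast is None:
        peak = np.max(np.abs(img))
        img = img / peak if peak > 0 else img
    else:
        sd = img.std()
        img = np.clip(img * (contrast / sd), -1.0, 1.0) if sd > 0 else img
    return ImageSequence(img[:, :, None], meta={"source": str(path)})


def orientation_energy_ratio(image: np.ndarray) -> float:
    """Cardinal:oblique energy ratio of the image's amplitude spectrum.

    Frequency samples are binned by the angle of their frequency vector:
    within +-22.5 deg of an axis counts as cardinal, the rest as oblique.
    The DC term is excluded.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 3:
        img = img.mean(axis=2)
    n0, n1 = img.shape
    # Hann window: suppresses the spurious cardinal energy of the FFT's
    # periodic wrap discontinuity on non-periodic images
    win = np.outer(np.hanning(n0), np.hanning(n1))
    img = (img - img.mean()) * win
    spec = np.abs(np.fft.fft2(img)) ** 2
    fx = np.fft.fftfreq(n1)[None, :]
    fy = np.fft.fftfreq(n0)[:, None]
    rho = np.hypot(fx, fy)
    phi = np.rad2deg(np.arctan2(fy, fx)) % 90.0
    cardinal = (phi <= 22.5) | (phi > 67.5)
    # whiten radially so the radial spectrum (and the coarse angular
    # sampling of the lowest frequency rings) cannot bias the census
    ring = np.round(rho * max(n0, n1)).astype(int)
    white = np.zeros_like(spec)
    for r in np.unique(ring):
        if r == 0:
            continue
        sel = ring == r
        m = spec[sel].mean()
        if m > 0:
            white[sel] = spec[sel] / m
    mask = ring > 0
    e_card = white[cardinal & mask].mean()
    e_obl = white[(~cardinal) & mask].mean()
    return float(e_card / e_obl)


def lag1_autocorrelation(image: np.ndarray) -> float:
    """Mean of horizontal and vertical lag-1 spatial autocorrelation."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 3:
        img = img[:, :, 0]
    img = img - img.mean()
    denom = np.mean(img**2)
    if denom == 0:
        return 0.0
    ach = np.mean(img[:, :-1] * img[:, 1:]) / denom
    acv = np.mean(img[:-1, :] * img[1:, :]) / denom
    return float((ach + acv) / 2.0)


# ---------------------------------------------------------------------------
# translation


def translate_sequence(
    source: ImageSequence | np.ndarray,
    v: Velocity,
    n_frames: int = N_FRAMES,
    patch: int = PATCH_SIZE,
    origin: tuple[float, float] | None = None,
    method: Literal["bilinear", "fourier"] = "bilinear",
) -> ImageSequence:
    """Rigidly translate ``source`` content at velocity ``v`` behind a window.

    Frame t samples the source at an offset of ``-t * v`` (content moving at
    +v sweeps the sampling window backwards across the source).  Subpixel
    positions are rendered by bilinear interpolation by default; a
    Fourier-shift sampler is available for band-limited sources.

    ``origin`` is the (row, col) of the window's top-left corner in frame 0;
    when omitted the window is centred on the feasible region.  A window
    that would leave the source raises ``ValueError`` (no wraparound).
    """
    src = source.pixels[:, :, 0] if isinstance(source, ImageSequence) else np.asarray(source)
    if src.ndim == 3:
        src = src[:, :, 0]
    h, w = src.shape
    dcol, drow = velocity_to_screen(v)
    # sampling offsets are the negation of the content displacement
    t = np.arange(n_frames)
    off_r = -t * drow
    off_c = -t * dcol
    lo_r, hi_r = off_r.min(), off_r.max()
    lo_c, hi_c = off_c.min(), off_c.max()
    if origin is None:
        # centre of the feasible interval [-lo, dim - patch - hi]
        origin = ((h - patch - (hi_r + lo_r)) / 2.0, (w - patch - (hi_c + lo_c)) / 2.0)
    r0, c0 = origin
    if (
        r0 + lo_r < -1e-9
        or c0 + lo_c < -1e-9
        or r0 + hi_r + patch - 1 > h - 1 + 1e-9
        or c0 + hi_c + patch - 1 > w - 1 + 1e-9
    ):
        raise ValueError(
            f"moving {patch} px window leaves the {h}x{w} source "
            f"(origin {origin}, velocity {v})"
        )
    rows = np.arange(patch)
    cols = np.arange(patch)
    frames = np.empty((patch, patch, n_frames), dtype=np.float32)
    if method == "bilinear":
        for k in range(n_frames):
            rr = rows + r0 + off_r[k]
            cc = cols + c0 + off_c[k]
            grid_r, grid_c = np.meshgrid(rr, cc, indexing="ij")
            frames[:, :, k] = ndimage.map_coordinates(src, [grid_r, grid_c], order=1)
    elif method == "fourier":
        fsrc = np.fft.fft2(src)
        ky = np.fft.fftfreq(h)[:, None]
        kx = np.fft.fftfreq(w)[None, :]
        ri = int(np.floor(r0))
        ci = int(np.floor(c0))
        fr_sub, fc_sub = r0 - ri, c0 - ci
        for k in range(n_frames):
            shift_r = fr_sub + off_r[k]
            shift_c = fc_sub + off_c[k]
            # sampling at x + s equals shifting content by -s
            phase = np.exp(2j * np.pi * (ky * shift_r + kx * shift_c))
            shifted = np.real(np.fft.ifft2(fsrc * phase))
            frames[:, :, k] = shifted[ri : ri + patch, ci : ci + patch]
    else:
        raise ValueError(f"unknown interpolation method {method!r}")
    return ImageSequence(frames, velocity=v)


# ---------------------------------------------------------------------------
# dot worlds


@dataclass(frozen=True)
class DotWorldConfig:
    """Random dot training world (orientation-free control corpus)."""

    n_dots: tuple[int, int] = (1, 10)
    diameter: tuple[float, float] = (8.0, 16.0)
    contrast_range: tuple[float, float] = (-1.0, 1.0)
    background: float = 0.0
    distortion_axis: Literal["none", "cardinal", "oblique"] = "none"
    distortion_factor: float = 4.0

    def __post_init__(self) -> None:
        if not (1 <= self.n_dots[0] <= self.n_dots[1]):
            raise ValueError("invalid dot count range")
        if self.diameter[0] <= 0 or self.diameter[1] < self.diameter[0]:
            raise ValueError("invalid diameter range")
        if self.distortion_axis not in ("none", "cardinal", "oblique"):
            raise ValueError(f"unknown distortion_axis {self.distortion_axis!r}")


def _draw_ellipse(
    canvas: np.ndarray,
    cy: float,
    cx: float,
    ry: float,
    rx: float,
    angle_deg: float,
    value: float,
) -> None:
    """Composite an anti-aliased filled ellipse onto ``canvas`` (occluding)."""
    h, w = canvas.shape
    rmax = max(rx, ry) + 1.5
    r_lo = max(int(np.floor(cy - rmax)), 0)
    r_hi = min(int(np.ceil(cy + rmax)) + 1, h)
    c_lo = max(int(np.floor(cx - rmax)), 0)
    c_hi = min(int(np.ceil(cx + rmax)) + 1, w)
    if r_lo >= r_hi or c_lo >= c_hi:
        return
    yy, xx = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    dy = yy - cy
    dx = xx - cx
    th = np.deg2rad(angle_deg)
    # rotate into the ellipse frame (y-up handled implicitly: rotation of an
    # ellipse is its own mirror symmetric, so the screen-row sign is moot)
    u = dx * np.cos(th) + dy * np.sin(th)
    q = -dx * np.sin(th) + dy * np.cos(th)
    rho = np.hypot(u / rx, q / ry)
    cov = np.clip(0.5 - (rho - 1.0) * min(rx, ry), 0.0, 1.0)
    region = canvas[r_lo:r_hi, c_lo:c_hi]
    canvas[r_lo:r_hi, c_lo:c_hi] = cov * value + (1.0 - cov) * region


def make_dot_sequence(
    cfg: DotWorldConfig,
    v: Velocity,
    rng: np.random.Generator,
    size: int = PATCH_SIZE,
    n_frames: int = N_FRAMES,
) -> ImageSequence:
    """Dots translating rigidly at ``v``; no wraparound at the edges.

    Dots are placed uniformly within the image extended by the maximum
    traversal distance, so dots may enter or leave the frame.  With a
    distortion axis set, each dot's width is halved and its height doubled
    twice (net 4:1 aspect) and the dot is rotated onto the stated axis.
    """
    n = int(rng.integers(cfg.n_dots[0], cfg.n_dots[1] + 1))
    margin = MAX_TRAVERSAL
    centers = rng.uniform(-margin, size + margin, size=(n, 2))
    diams = rng.uniform(cfg.diameter[0], cfg.diameter[1], size=n)
    values = rng.uniform(cfg.contrast_range[0], cfg.contrast_range[1], size=n)
    if cfg.distortion_axis == "cardinal":
        angles = rng.choice([0.0, 90.0], size=n)
    elif cfg.distortion_axis == "oblique":
        angles = rng.choice([45.0, 135.0], size=n)
    else:
        angles = np.zeros(n)
    stretch = np.sqrt(cfg.distortion_factor)
    dcol, drow = velocity_to_screen(v)
    frames = np.full((size, size, n_frames), cfg.background, dtype=np.float32)
    for k in range(n_frames):
        canvas = frames[:, :, k].astype(np.float64)
        for i in range(n):
            r = diams[i] / 2.0
            if cfg.distortion_axis == "none":
                ry = rx = r
            else:
                ry, rx = r * stretch, r / stretch  # height doubled, width halved
            _draw_ellipse(
                canvas,
                centers[i, 0] + k * drow,
                centers[i, 1] + k * dcol,
                ry,
                rx,
                angles[i],
                values[i],
            )
        frames[:, :, k] = canvas
    return ImageSequence(np.clip(frames, -1.0, 1.0), velocity=v)


# ---------------------------------------------------------------------------
# sequence generators (rng, velocity) -> ImageSequence


def texture_sequence_generator(
    cfg: TextureConfig | None = None, method: str = "bilinear"
) -> SequenceGenerator:
    """Generator drawing a fresh texture per sequence and translating it."""
    cfg = cfg or TextureConfig()

    def gen(rng: np.random.Generator, v: Velocity) -> ImageSequence:
        tex = generate_texture(cfg, rng)
        src = tex.pixels[:, :, 0]
        h, w = src.shape
        dcol, drow = velocity_to_screen(v)
        t = np.arange(N_FRAMES)
        off_r = -t * drow
        off_c = -t * dcol
        r0 = rng.uniform(-min(off_r.min(), 0), h - PATCH_SIZE - max(off_r.max(), 0))
        c0 = rng.uniform(-min(off_c.min(), 0), w - PATCH_SIZE - max(off_c.max(), 0))
        return translate_sequence(src, v, origin=(r0, c0), method=method)

    return gen


def dot_sequence_generator(cfg: DotWorldConfig | None = None) -> SequenceGenerator:
    cfg = cfg or DotWorldConfig()

    def gen(rng: np.random.Generator, v: Velocity) -> ImageSequence:
        return make_dot_sequence(cfg, v, rng)

    return gen


# ---------------------------------------------------------------------------
# training sets


@dataclass
class TrainingSet:
    """Labelled corpus of 32 x 32 x 6 sequences with a 70/15/15 split."""

    X: np.ndarray  # (N, 32, 32, 6) float32
    y: np.ndarray  # (N,) int64 class labels 0..63
    split: np.ndarray  # (N,) int8: 0 train, 1 validation, 2 test
    seed: int
    meta: dict = field(default_factory=dict)

    TRAIN, VAL, TEST = 0, 1, 2

    def indices(self, which: int) -> np.ndarray:
        return np.flatnonzero(self.split == which)

    @property
    def n_train(self) -> int:
        return int(np.sum(self.split == self.TRAIN))

    def subset(self, which: int) -> tuple[np.ndarray, np.ndarray]:
        idx = self.indices(which)
        return self.X[idx], self.y[idx]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(path, X=self.X, y=self.y, split=self.split)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps({"seed": self.seed, "meta": self.meta}, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TrainingSet":
        path = Path(path)
        data = np.load(path if path.suffix else path.with_suffix(".npz"))
        sidecar = path.with_suffix(".json")
        info = json.loads(sidecar.read_text()) if sidecar.exists() else {"seed": -1, "meta": {}}
        return cls(data["X"], data["y"], data["split"], info["seed"], info["meta"])


def _split_assignment(n_total: int, rng: np.random.Generator) -> np.ndarray:
    n_train = int(round(0.70 * n_total))
    n_val = int(round(0.15 * n_total))
    split = np.full(n_total, TrainingSet.TEST, dtype=np.int8)
    order = rng.permutation(n_total)
    split[order[:n_train]] = TrainingSet.TRAIN
    split[order[n_train : n_train + n_val]] = TrainingSet.VAL
    return split


def _class_counts(n_per_class: int, world: str) -> np.ndarray:
    """Per-class sequence counts (64,), optionally speed-reweighted.

    In a *slow* world counts fall linearly with speed rank so that the
    slowest class holds twice as many sequences as the fastest (which keeps
    ``n_per_class``); a *fast* world mirrors that.  Direction classes stay
    balanced.
    """
    counts = np.full(64, n_per_class, dtype=int)
    if world == "none":
        return counts
    ranks = np.arange(8) / 7.0  # 0 = slowest ... 1 = fastest
    if world == "slow":
        factor = 2.0 - ranks
    elif world == "fast":
        factor = 1.0 + ranks
    else:
        raise ValueError(f"unknown speed world {world!r}")
    per_speed = np.round(n_per_class * factor).astype(int)
    for i_speed in range(8):
        counts[i_speed::8] = per_speed[i_speed]
    return counts


def build_training_set(
    generator: SequenceGenerator,
    n_per_class: int = 1000,
    seed: int = 0,
    speed_world: Literal["none", "slow", "fast"] = "none",
) -> TrainingSet:
    """Balanced labelled corpus over the 64 trained velocities.

    Intensities are rescaled into [-1, 1] per sequence only when they
    exceed the bounds.  The result is bit-reproducible for a given seed.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    counts = _class_counts(n_per_class, speed_world)
    X_list, y_list = [], []
    for ci in range(64):
        vel = class_velocity(ci)
        for _ in range(counts[ci]):
            seq = generator(rng, vel)
            X_list.append(rescale_to_unit(seq.pixels))
            y_list.append(ci)
    X = np.stack(X_list).astype(np.float32)
    y = np.asarray(y_list, dtype=np.int64)
    split = _split_assignment(len(y), rng)
    return TrainingSet(X, y, split, seed, meta={"n_per_class": n_per_class, "speed_world": speed_world})


def reweight_speed_distribution(
    generator: SequenceGenerator,
    world: Literal["slow", "fast", "none"],
    n_per_class: int = 1000,
    seed: int = 0,
) -> TrainingSet:
    """Corpus whose speed histogram is tilted (2:1 slow or fast excess)."""
    return build_training_set(generator, n_per_class, seed, speed_world=world)


# ---------------------------------------------------------------------------
# corpus statistics and manipulations


def spatiotemporal_contrast(seq: ImageSequence | np.ndarray) -> float:
    """SD of all pixel intensities across space and frames."""
    px = seq.pixels if isinstance(seq, ImageSequence) else np.asarray(seq)
    if px.size == 0:
        raise ValueError("empty sequence")
    return float(np.std(px))


def corpus_speed_contrast_correlation(ts: TrainingSet) -> float:
    """Pearson correlation between ground-truth speed and sequence contrast."""
    speeds = TRAINED_SPEEDS[ts.y % 8]
    contrasts = ts.X.std(axis=(1, 2, 3))
    return float(np.corrcoef(speeds, contrasts)[0, 1])


def reverse_speed_contrast(ts: TrainingSet) -> TrainingSet:
    """Invert the corpus's speed-contrast association.

    Each sequence is scaled multiplicatively about its mean intensity by
    the gain that maps the mean contrast of its speed class onto the mean
    contrast of the rank-mirrored speed class, so the positive speed to
    spatiotemporal-contrast correlation of an autocorrelated corpus comes
    out negative.  Sequences pushed outside [-1, 1] are rescaled back in;
    zero-contrast sequences are left unchanged (with a warning).
    """
    speeds_idx = ts.y % 8
    contrasts = ts.X.std(axis=(1, 2, 3))
    mean_c = np.array(
        [contrasts[speeds_idx == i].mean() if np.any(speeds_idx == i) else 0.0 for i in range(8)]
    )
    target = mean_c[::-1]  # mirror across speed rank
    gains = np.where(mean_c > 0, target / np.where(mean_c > 0, mean_c, 1.0), 1.0)
    X_new = np.empty_like(ts.X)
    n_flat = 0
    for i in range(len(ts.y)):
        x = ts.X[i]
        if contrasts[i] == 0:
            X_new[i] = x
            n_flat += 1
            continue
        m = x.mean()
        scaled = m + (x - m) * gains[speeds_idx[i]]
        X_new[i] = rescale_to_unit(scaled)
    if n_flat:
        warnings.warn(f"{n_flat} zero-contrast sequences left unchanged")
    meta = dict(ts.meta, reverse_speed_contrast=True)
    return TrainingSet(X_new, ts.y.copy(), ts.split.copy(), ts.seed, meta)


def blur_or_sharpen(
    ts: TrainingSet, mode: Literal["blur", "sharpen"], sigma: float = 20.0
) -> TrainingSet:
    """Raise (blur) or lower (sharpen) the corpus's spatial autocorrelation.

    Blur convolves each frame with a spatial Gaussian of SD ``sigma`` px;
    sharpen applies the complementary unsharp mask (2 I - blur(I)).  A
    sigma of 0 is the identity.
    """
    if mode not in ("blur", "sharpen"):
        raise ValueError(f"mode must be 'blur' or 'sharpen', got {mode!r}")
    if sigma == 0:
        return TrainingSet(ts.X.copy(), ts.y.copy(), ts.split.copy(), ts.seed, dict(ts.meta))
    X_new = np.empty_like(ts.X)
    for i in range(len(ts.y)):
        low = ndimage.gaussian_filter(
            ts.X[i].astype(np.float64), sigma=(sigma, sigma, 0), mode="nearest"
        )
        out = low if mode == "blur" else 2.0 * ts.X[i] - low
        X_new[i] = rescale_to_unit(out)
    meta = dict(ts.meta, filter=mode, filter_sigma=sigma)
    return TrainingSet(X_new, ts.y.copy(), ts.split.copy(), ts.seed, meta)


def corpus_lag1_autocorrelation(ts: TrainingSet, max_sequences: int = 500) -> float:
    """Mean lag-1 spatial autocorrelation over (a subsample of) the corpus."""
    n = min(len(ts.y), max_sequences)
    return float(np.mean([lag1_autocorrelation(ts.X[i][:, :, 0]) for i in range(n)]))
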