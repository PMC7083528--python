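"""Laboratory stimulus battery: gratings, plaids, barber poles, dots, rhombi.

All stimuli are 32 x 32 x 6 pixel sequences in [-1, 1].  Contrast follows
the max-minus-min convention: the ratio between the maximal intensity
difference in a sequence and the maximal difference the input can carry,
so contrast 1 spans [-1, 1] and ``measure_contrast`` returns
(max - min) / 2.

Gratings drift; dots and rhombi translate rigidly with coverage-based
anti-aliased edges so that subpixel motion introduces no frame-rate
artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .types import N_FRAMES, PATCH_SIZE, ImageSequence, Velocity, velocity_to_screen


def measure_contrast(seq: ImageSequence | np.ndarray) -> float:
    """(max - min) / 2 of the sequence on the [-1, 1] intensity scale."""
    px = seq.pixels if isinstance(seq, ImageSequence) else np.asarray(seq)
    if px.size == 0:
        raise ValueError("empty sequence")
    return float((px.max() - px.min()) / 2.0)


# ---------------------------------------------------------------------------
# gratings


@dataclass(frozen=True)
class GratingSpec:
    """Drifting sinusoid.

    Speed may be given directly (px/frame) or via ``temporal_frequency``
    (cycles/frame, converted as speed = tf * spatial_frequency).  Direction
    is the drift direction; the stripes are orthogonal to it.
    """

    spatial_frequency: float = 16.0  # px/cycle
    direction: float = 0.0  # degrees, 0 = rightward, CCW positive
    speed: float | None = None  # px/frame
    temporal_frequency: float | None = None  # cycles/frame
    phase: float = 0.0  # degrees
    contrast: float = 1.0
    size: int = PATCH_SIZE
    n_frames: int = N_FRAMES

    def __post_init__(self) -> None:
        if self.spatial_frequency <= 0:
            raise ValueError("spatial frequency must be positive")
        if self.speed is not None and self.temporal_frequency is not None:
            implied = self.temporal_frequency * self.spatial_frequency
            if abs(implied - self.speed) > 1e-9:
                raise ValueError(
                    f"speed {self.speed} inconsistent with temporal_frequency "
                    f"({implied} px/frame implied)"
                )

    @property
    def speed_px(self) -> float:
        if self.speed is not None:
            return self.speed
        if self.temporal_frequency is not None:
            return self.temporal_frequency * self.spatial_frequency
        return 0.0


def make_grating(spec: GratingSpec) -> ImageSequence:
    th = np.deg2rad(spec.direction)
    n = spec.size
    cols = np.arange(n)[None, :, None]
    rows = np.arange(n)[:, None, None]
    t = np.arange(spec.n_frames)[None, None, :]
    # projection of (x, y-up) position onto the drift direction
    proj = cols * np.cos(th) + (-rows) * np.sin(th)
    phase = 2.0 * np.pi * (proj - spec.speed_px * t) / spec.spatial_frequency
    px = spec.contrast * np.sin(phase + np.deg2rad(spec.phase))
    return ImageSequence(
        px.astype(np.float32), velocity=Velocity(spec.direction, spec.speed_px)
    )


# ---------------------------------------------------------------------------
# plaids


@dataclass(frozen=True)
class PlaidSpec:
    """Two superimposed gratings; frames are the clipped sum of components.

    Component drift directions sit symmetrically about ``direction`` at
    ``separation`` degrees apart.  ``speeds`` and ``contrasts`` are per
    component.
    """

    direction: float = 0.0
    separation: float = 90.0
    speeds: tuple[float, float] = (0.8, 0.8)
    contrasts: tuple[float, float] = (0.5, 0.5)
    spatial_frequency: float = 16.0
    phases: tuple[float, float] = (0.0, 0.0)
    size: int = PATCH_SIZE
    n_frames: int = N_FRAMES

    def __post_init__(self) -> None:
        if min(self.contrasts) < 0:
            raise ValueError("component contrasts must be >= 0")
        if sum(self.contrasts) == 0:
            raise ValueError("total contrast must be positive")

    def component_specs(self) -> tuple[GratingSpec, GratingSpec]:
        half = self.separation / 2.0
        return tuple(
            GratingSpec(
                spatial_frequency=self.spatial_frequency,
                direction=self.direction + sign * half,
                speed=self.speeds[i],
                phase=self.phases[i],
                contrast=self.contrasts[i],
                size=self.size,
                n_frames=self.n_frames,
            )
            for i, sign in enumerate((+1, -1))
        )


def make_plaid(spec: PlaidSpec) -> ImageSequence:
    c1, c2 = spec.component_specs()
    px = make_grating(c1).pixels + make_grating(c2).pixels
    return ImageSequence(np.clip(px, -1.0, 1.0), meta={"degenerate": spec.separation % 180 == 0})


def unikinetic_plaid(
    separation: float,
    moving_speed: float = 3.8,
    direction: float = 0.0,
    contrasts: tuple[float, float] = (0.5, 0.5),
    phases: tuple[float, float] = (0.0, 0.0),
) -> ImageSequence:
    """Plaid with one static component; the other drifts at ``moving_speed``.

    The moving component drifts in ``direction``; the static component's
    drift axis is rotated ``separation`` degrees away.  A separation of 0
    degenerates to a single (flagged) grating.
    """
    spec = PlaidSpec(
        direction=direction + separation / 2.0,
        separation=separation,
        speeds=(0.0, moving_speed),
        contrasts=contrasts,
        phases=phases,
    )
    seq = make_plaid(spec)
    seq.meta["degenerate"] = separation == 0.0
    seq.meta["moving_direction"] = direction
    return seq


# ---------------------------------------------------------------------------
# barber poles


@dataclass(frozen=True)
class BarberPoleSpec:
    """Oblique grating seen through an elongated rectangular aperture."""

    aspect_ratio: int = 1  # height : width of the unmasked region, 1..16
    grating_direction: float = 135.0  # oblique drift
    speed: float = 0.8
    contrast: float = 1.0
    spatial_frequency: float = 16.0
    phase: float = 0.0
    size: int = PATCH_SIZE

    def __post_init__(self) -> None:
        if not 1 <= self.aspect_ratio <= 16:
            raise ValueError("aspect ratio must lie in 1..16")


def _aperture_dims(ratio: int, size: int) -> tuple[int, int]:
    """Unmasked (height, width) with exact height:width ratio, maximal area.

    Both pairs of edges may be masked; among integer (h, w) with
    h = ratio * w and h <= size the largest area always exists for
    ratio <= size / 2.
    """
    best = None
    for w in range(1, size + 1):
        h = ratio * w
        if h > size:
            break
        if best is None or h * w > best[0] * best[1]:
            best = (h, w)
    if best is None:
        raise ValueError(f"aspect ratio {ratio} unattainable within {size} px")
    return best


def make_barber_pole(spec: BarberPoleSpec) -> ImageSequence:
    h, w = _aperture_dims(spec.aspect_ratio, spec.size)
    g = make_grating(
        GratingSpec(
            spatial_frequency=spec.spatial_frequency,
            direction=spec.grating_direction,
            speed=spec.speed,
            phase=spec.phase,
            contrast=spec.contrast,
            size=spec.size,
        )
    )
    mask = np.zeros((spec.size, spec.size, 1), dtype=np.float32)
    r0 = (spec.size - h) // 2
    c0 = (spec.size - w) // 2
    mask[r0 : r0 + h, c0 : c0 + w, 0] = 1.0
    seq = ImageSequence(g.pixels * mask, meta={"aperture": (h, w)})
    return seq


# ---------------------------------------------------------------------------
# dot kinematograms


@dataclass(frozen=True)
class DotMotionSpec:
    """White-dot kinematogram: 12 dots, radius 5 px, black background.

    With ``coherent_fraction`` < 1 the remaining dots move at the same
    speed in ``distractor_direction`` (motion-opponency probes).  Dots
    wrap around the image edges; overlap occludes.
    """

    n_dots: int = 12
    radius: float = 5.0
    dot_value: float = 1.0
    background: float = -1.0
    coherent_fraction: float = 1.0
    distractor_direction: float | None = None
    size: int = PATCH_SIZE
    n_frames: int = N_FRAMES

    def __post_init__(self) -> None:
        if self.n_dots < 1 or self.radius <= 0:
            raise ValueError("invalid dot count or radius")


def _draw_wrapped_disc(canvas: np.ndarray, cy: float, cx: float, r: float, value: float) -> None:
    size = canvas.shape[0]
    cy %= size
    cx %= size
    for oy in (-size, 0, size):
        for ox in (-size, 0, size):
            yc, xc = cy + oy, cx + ox
            if yc < -r - 1 or yc > size + r or xc < -r - 1 or xc > size + r:
                continue
            r_lo = max(int(np.floor(yc - r - 1)), 0)
            r_hi = min(int(np.ceil(yc + r + 1)) + 1, size)
            c_lo = max(int(np.floor(xc - r - 1)), 0)
            c_hi = min(int(np.ceil(xc + r + 1)) + 1, size)
            if r_lo >= r_hi or c_lo >= c_hi:
                continue
            yy, xx = np.mgrid[r_lo:r_hi, c_lo:c_hi]
            dist = np.hypot(yy - yc, xx - xc)
            cov = np.clip(r + 0.5 - dist, 0.0, 1.0)
            region = canvas[r_lo:r_hi, c_lo:c_hi]
            canvas[r_lo:r_hi, c_lo:c_hi] = cov * value + (1.0 - cov) * region


def make_dot_stimulus(
    spec: DotMotionSpec, v: Velocity, rng: np.random.Generator
) -> ImageSequence:
    """Render a dot kinematogram translating at ``v`` (wraparound edges).

    In opponent mode (coherent_fraction 0.66 of 12 dots -> 8 probe dots,
    nearest-integer split) the remaining 4 dots move at the probe speed in
    the distractor direction.
    """
    n_probe = int(round(spec.coherent_fraction * spec.n_dots))
    n_dist = spec.n_dots - n_probe
    if n_dist > 0 and spec.distractor_direction is None:
        raise ValueError("distractor_direction required when coherent_fraction < 1")
    centers = rng.uniform(0, spec.size, size=(spec.n_dots, 2))  # (row, col)
    d_probe = velocity_to_screen(v)
    d_dist = (
        velocity_to_screen(Velocity(spec.distractor_direction, v.speed))
        if n_dist > 0
        else (0.0, 0.0)
    )
    frames = np.full((spec.size, spec.size, spec.n_frames), spec.background, dtype=np.float32)
    for k in range(spec.n_frames):
        canvas = frames[:, :, k].astype(np.float64)
        for i in range(spec.n_dots):
            dcol, drow = d_probe if i < n_probe else d_dist
            _draw_wrapped_disc(
                canvas,
                centers[i, 0] + k * drow,
                centers[i, 1] + k * dcol,
                spec.radius,
                spec.dot_value,
            )
        frames[:, :, k] = canvas
    return ImageSequence(np.clip(frames, -1.0, 1.0), velocity=v)


# ---------------------------------------------------------------------------
# rhombi


@dataclass(frozen=True)
class RhombusSpec:
    """Rigidly translating filled rhombus on a black background.

    The rhombus is ``height`` px tall with width = height * aspect_ratio,
    oriented ``orientation`` degrees clockwise from vertical, and moves
    rightward at ``speed`` px/frame.  The fill level is set so that
    (max - min) / 2 equals ``contrast`` on the -1 background.
    """

    height: float = 16.0
    aspect_ratio: float = 0.1  # thin 0.1, wide 0.8
    orientation: float = 40.0  # degrees clockwise from vertical
    speed: float = 3.8
    direction: float = 0.0
    contrast: float = 1.0
    background: float = -1.0
    size: int = PATCH_SIZE
    n_frames: int = N_FRAMES
    oversample: int = 4

    def __post_init__(self) -> None:
        if self.contrast <= 0:
            raise ValueError("contrast must be positive")

    @property
    def width(self) -> float:
        return self.height * self.aspect_ratio

    def vertices(self) -> np.ndarray:
        """Corner (x, y-up) coordinates about the centroid, rotated."""
        pts = np.array(
            [
                [0.0, self.height / 2.0],
                [self.width / 2.0, 0.0],
                [0.0, -self.height / 2.0],
                [-self.width / 2.0, 0.0],
            ]
        )
        th = -np.deg2rad(self.orientation)  # clockwise from vertical
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        return pts @ rot.T

    def edge_normals(self) -> np.ndarray:
        """Outward unit normals (x, y-up) of the two distinct edge pairs."""
        vtx = self.vertices()
        normals = []
        for i in range(2):
            e = vtx[(i + 1) % 4] - vtx[i]
            n = np.array([e[1], -e[0]])
            normals.append(n / np.linalg.norm(n))
        return np.array(normals)


def make_rhombus(spec: RhombusSpec) -> ImageSequence:
    fill = spec.background + 2.0 * spec.contrast
    vtx = spec.vertices()
    # half-plane representation: inside iff n . (p - v) <= 0 for all edges
    normals, offsets = [], []
    for i in range(4):
        a, b = vtx[i], vtx[(i + 1) % 4]
        e = b - a
        n = np.array([e[1], -e[0]])
        if np.dot(n, -a) > 0:  # orient outward (centroid at origin)
            n = -n
        normals.append(n)
        offsets.append(np.dot(n, a))
    normals = np.array(normals)
    offsets = np.array(offsets)

    s = spec.oversample
    n_px = spec.size
    sub = (np.arange(n_px * s) + 0.5) / s - 0.5
    cx0 = n_px / 2.0 - 0.5
    dcol, drow = velocity_to_screen(Velocity(spec.direction, spec.speed))
    # centre the whole trajectory in the window
    start_col = cx0 - dcol * (spec.n_frames - 1) / 2.0
    start_row = cx0 - drow * (spec.n_frames - 1) / 2.0
    frames = np.empty((n_px, n_px, spec.n_frames), dtype=np.float32)
    for k in range(spec.n_frames):
        px = sub[None, :] - (start_col + k * dcol)
        py = -(sub[:, None] - (start_row + k * drow))  # y up
        inside = np.ones((n_px * s, n_px * s), dtype=bool)
        for n_vec, off in zip(normals, offsets):
            inside &= n_vec[0] * px + n_vec[1] * py <= off
        cov = inside.reshape(n_px, s, n_px, s).mean(axis=(1, 3))
        frames[:, :, k] = spec.background + cov * (fill - spec.background)
    return ImageSequence(frames, velocity=Velocity(spec.direction, spec.speed))


# ---------------------------------------------------------------------------
# export


def save_frames(seq: ImageSequence, path, spec=None) -> None:
    """Export a sequence as a multi-frame TIFF plus a JSON spec sidecar.

    Intensities in [-1, 1] are mapped to 16-bit grey levels; the sidecar
    records the generating spec (dataclass or dict) and ground truth.
    """
    import json
    from dataclasses import asdict, is_dataclass
    from pathlib import Path

    import tifffile

    path = Path(path)
    frames = np.moveaxis(seq.pixels, 2, 0)  # (T, H, W)
    as_u16 = np.round((frames + 1.0) / 2.0 * 65535.0).astype(np.uint16)
    tifffile.imwrite(path, as_u16)
    meta = {
        "spec": asdict(spec) if is_dataclass(spec) else (spec or {}),
        "velocity": None
        if seq.velocity is None
        else {"direction": seq.velocity.direction, "speed": seq.velocity.speed},
        "intensity_range": [-1.0, 1.0],
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=float))


# ---------------------------------------------------------------------------
# protocol series


def speed_ratio_series(
    ratios: Sequence[float] | None = None, base_speed: float = 0.8
) -> list[PlaidSpec]:
    """90-degree plaids whose component speed ratio spans 0.5:1 to 2:1."""
    if ratios is None:
        ratios = np.linspace(0.5, 2.0, 16)
    return [
        PlaidSpec(direction=0.0, separation=90.0, speeds=(base_speed, base_speed * r))
        for r in ratios
    ]


def contrast_ratio_series(
    total_contrasts: Sequence[float] = (0.005, 0.01, 0.02, 0.04),
    n_steps: int = 8,
    speed: float = 3.8,
) -> list[PlaidSpec]:
    """90-degree plaids with log component-contrast ratios 0..0.6."""
    specs = []
    for total in total_contrasts:
        for log_ratio in np.linspace(0.0, 0.6, n_steps):
            r = 10.0**log_ratio
            c1 = total * r / (1.0 + r)
            c2 = total / (1.0 + r)
            specs.append(
                PlaidSpec(
                    direction=0.0,
                    separation=90.0,
                    speeds=(speed, speed),
                    contrasts=(c1, c2),
                )
            )
    return specs
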