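"""Core domain objects: image sequences and velocities.

Conventions used throughout the package:

* direction 0 deg points rightward, angles increase counter-clockwise,
  and the y axis points *up*;
* pixel arrays store row 0 at the top of the image, so the screen-space
  row displacement is the negative of the mathematical y displacement.
  :func:`velocity_to_screen` is the single place where that sign flip
  happens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: the 8 trained directions (degrees); 4 cardinal followed by 4 oblique order
TRAINED_DIRECTIONS = np.arange(8) * 45.0
#: the 8 trained speeds (pixels/frame), linearly spaced
TRAINED_SPEEDS = np.linspace(0.8, 3.8, 8)
CARDINAL_DIRECTIONS = (0.0, 90.0, 180.0, 270.0)
OBLIQUE_DIRECTIONS = (45.0, 135.0, 225.0, 315.0)

N_CLASSES = 64
PATCH_SIZE = 32
N_FRAMES = 6


@dataclass(frozen=True)
class Velocity:
    """Polar movement descriptor: direction in degrees, speed in px/frame."""

    direction: float
    speed: float

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise ValueError("speed must be non-negative")
        d = float(self.direction) % 360.0
        object.__setattr__(self, "direction", 0.0 if d >= 360.0 else d)
        object.__setattr__(self, "speed", float(self.speed))

    @property
    def cartesian(self) -> tuple[float, float]:
        """(x, y) components with y pointing up."""
        th = np.deg2rad(self.direction)
        return self.speed * float(np.cos(th)), self.speed * float(np.sin(th))

    def is_cardinal(self) -> bool:
        return self.direction % 90.0 == 0.0


def velocity_to_screen(v: Velocity) -> tuple[float, float]:
    """Per-frame (column, row) displacement of *v* in array coordinates.

    Row displacement is negated relative to the mathematical y component
    because row indices grow downward.
    """
    dx, dy = v.cartesian
    return dx, -dy


def class_index(v: Velocity) -> int:
    """Label of a trained velocity on the 8-direction x 8-speed grid.

    Classes are ordered direction-major: ``index = 8 * i_dir + i_speed``.
    """
    i_dir = int(np.argmin(np.abs((TRAINED_DIRECTIONS - v.direction + 180) % 360 - 180)))
    i_speed = int(np.argmin(np.abs(TRAINED_SPEEDS - v.speed)))
    return 8 * i_dir + i_speed


def class_velocity(index: int) -> Velocity:
    """Inverse of :func:`class_index`."""
    if not 0 <= index < N_CLASSES:
        raise ValueError(f"class index {index} outside [0, {N_CLASSES})")
    return Velocity(TRAINED_DIRECTIONS[index // 8], TRAINED_SPEEDS[index % 8])


@dataclass
class ImageSequence:
    """A height x width x frames stack of intensities in [-1, 1].

    ``velocity`` records the ground-truth translation when the sequence was
    produced by rigidly translating a source image.
    """

    pixels: np.ndarray
    velocity: Velocity | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[:, :, None]
        if self.pixels.ndim != 3 or self.pixels.shape[2] < 1:
            raise ValueError("pixels must be a (height, width, frames>=1) array")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape


def rescale_to_unit(pixels: np.ndarray) -> np.ndarray:
    """Scale intensities linearly into [-1, 1] only if they exceed bounds.

    Sequences already inside the bounds are returned untouched so that
    absolute contrast differences between sequences are preserved.
    """
    peak = float(np.max(np.abs(pixels)))
    if peak > 1.0:
        return pixels / peak
    return pixels


def circdiff(a, b):
    """Signed circular difference a - b wrapped to (-180, 180] degrees."""
    return -((b - a + 180.0) % 360.0 - 180.0)
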