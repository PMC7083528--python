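"""Continuous direction/speed decoding and psychometric fitting.

The classifier's output layer is a 64-unit direction x speed grid.  A
continuous direction estimate comes from fitting a von Mises bump

    G(x) = p + A * exp(kappa * (cos(x - x0) - 1))

to the 8 direction-labelled activations at the best-responding speed and
reporting the peak location x0 (reported width sigma = 1/sqrt(kappa)).
Speed is decoded analogously with a Gaussian bump over the 8
speed-labelled activations at the best direction.  Psychometric data are
fit by maximum likelihood with a cumulative Gaussian carrying symmetric
guess/lapse rates; the JND is taken as the fitted sigma (the 50%-to-84%
distance) and sensitivity as its reciprocal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .types import TRAINED_DIRECTIONS, TRAINED_SPEEDS, Velocity, circdiff
from .network import NetworkParams, mt_response
from .stimuli import DotMotionSpec, make_dot_stimulus


@dataclass
class TuningFitParams:
    """Descriptive bump model: offset p, amplitude A, peak x0, width sigma."""

    p: float
    A: float
    x0: float
    sigma: float
    converged: bool = True
    fallback: bool = False


@dataclass
class PsychometricFit:
    threshold: float  # 50% point of the underlying Gaussian (PSE)
    sigma: float  # slope parameter; JND
    lapse: float
    sensitivity: float  # 1 / JND
    n_levels: int
    degenerate: bool = False


# ---------------------------------------------------------------------------
# tuning-curve fits


def _von_mises(x_deg: np.ndarray, p: float, A: float, x0: float, kappa: float) -> np.ndarray:
    return p + A * np.exp(kappa * (np.cos(np.deg2rad(x_deg - x0)) - 1.0))


def fit_von_mises(x_deg: np.ndarray, y: np.ndarray) -> TuningFitParams:
    """Least-squares von Mises fit over direction-labelled responses.

    Falls back to the circular mean of the (offset-subtracted) responses
    when the optimiser fails or the data carry no modulation.
    """
    x_deg = np.asarray(x_deg, dtype=float)
    y = np.asarray(y, dtype=float)
    spread = y.max() - y.min()
    if spread <= 0 or not np.all(np.isfinite(y)):
        return TuningFitParams(float(y.mean()), 0.0, float("nan"), float("inf"), False, True)
    x0_init = x_deg[int(np.argmax(y))]
    p0 = [y.min(), spread, x0_init, 2.0]
    try:
        res = optimize.least_squares(
            lambda th: _von_mises(x_deg, *th) - y,
            p0,
            bounds=([-np.inf, 0.0, x0_init - 180.0, 1e-3], [np.inf, np.inf, x0_init + 180.0, 1e3]),
            max_nfev=2000,
        )
        p, A, x0, kappa = res.x
        if res.success and A > 0:
            return TuningFitParams(p, A, float(x0 % 360.0), float(1.0 / np.sqrt(kappa)))
    except Exception:
        pass
    w = y - y.min()
    ang = np.angle(np.sum(w * np.exp(1j * np.deg2rad(x_deg))))
    return TuningFitParams(float(y.min()), float(spread), float(np.rad2deg(ang) % 360.0), float("inf"), False, True)


def _gaussian(x: np.ndarray, p: float, A: float, x0: float, sigma: float) -> np.ndarray:
    return p + A * np.exp(-((x - x0) ** 2) / (2.0 * sigma**2))


def fit_gaussian(x: np.ndarray, y: np.ndarray) -> TuningFitParams:
    """Least-squares Gaussian fit over speed-labelled responses."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    spread = y.max() - y.min()
    if spread <= 0 or not np.all(np.isfinite(y)):
        return TuningFitParams(float(y.mean()), 0.0, float("nan"), float("inf"), False, True)
    x0_init = x[int(np.argmax(y))]
    dx = np.ptp(x)
    # peak location constrained to the physical axis (speeds cannot be
    # negative) extended by one grid span above
    x0_lo = max(0.0, x.min() - dx) if x.min() >= 0 else x.min() - dx
    p0 = [y.min(), spread, x0_init, dx / 4.0]
    try:
        res = optimize.least_squares(
            lambda th: _gaussian(x, *th) - y,
            p0,
            bounds=([-np.inf, 0.0, x0_lo, dx / 100.0], [np.inf, np.inf, x.max() + dx, 10.0 * dx]),
            max_nfev=2000,
        )
        p, A, x0, sigma = res.x
        if res.success and A > 0:
            return TuningFitParams(p, A, float(x0), float(sigma))
    except Exception:
        pass
    w = y - y.min()
    centroid = float(np.sum(w * x) / np.sum(w))
    return TuningFitParams(float(y.min()), float(spread), centroid, float("inf"), False, True)


# ---------------------------------------------------------------------------
# decodes from a 64-unit response


def decode_direction_from_response(mt: np.ndarray) -> tuple[float, TuningFitParams]:
    """Peak direction of the von Mises fit at the best-responding speed.

    ``mt`` is a (64,) response vector on the direction-major grid
    (index = 8 * i_direction + i_speed).
    """
    grid = np.asarray(mt, dtype=float).reshape(8, 8)  # (direction, speed)
    best_speed = int(np.argmax(grid) % 8)
    y = grid[:, best_speed]
    fit = fit_von_mises(TRAINED_DIRECTIONS, y)
    return fit.x0, fit

def decode_speed_from_response(mt: np.ndarray) -> tuple[float, TuningFitParams]:
    """Peak speed of the Gaussian fit at the best-responding direction."""
    grid = np.asarray(mt, dtype=float).reshape(8, 8)
    best_dir = int(np.argmax(grid) // 8)
    y = grid[best_dir, :]
    fit = fit_gaussian(TRAINED_SPEEDS, y)
    return fit.x0, fit


def population_direction_decode(
    net: NetworkParams, make_stim, base_direction: float = 0.0
) -> tuple[float, TuningFitParams]:
    """Aligned-population decode of a parametric stimulus.

    ``make_stim(direction)`` must return the stimulus pixels rotated so
    its nominal direction is ``direction``.  The stimulus is presented at
    each of the 8 trained directions, responses are rotated back onto a
    common axis and averaged before fitting; the returned estimate is
    relative to ``base_direction`` (added back in).
    """
    curves = []
    for i, d in enumerate(TRAINED_DIRECTIONS):
        mt = mt_response(net, make_stim(base_direction + d)[None])[0].reshape(8, 8)
        curves.append(np.roll(mt, -i, axis=0))
    mean = np.mean(curves, axis=0)
    x0, fit = decode_direction_from_response(mean.ravel())
    est = (base_direction + x0) % 360.0
    return est, fit


def decode_direction(net: NetworkParams, seq) -> float:
    """Continuous direction estimate for a single stimulus."""
    px = seq.pixels if hasattr(seq, "pixels") else np.asarray(seq)
    mt = mt_response(net, px[None])[0]
    return decode_direction_from_response(mt)[0]


def decode_speed(net: NetworkParams, seq) -> float:
    """Continuous speed estimate for a single stimulus."""
    px = seq.pixels if hasattr(seq, "pixels") else np.asarray(seq)
    mt = mt_response(net, px[None])[0]
    return decode_speed_from_response(mt)[0]


# ---------------------------------------------------------------------------
# psychometrics


def _psy_nll(theta, x, k, n):
    mu, log_sigma, lapse = theta
    sigma = np.exp(log_sigma)
    p = lapse + (1.0 - 2.0 * lapse) * stats.norm.cdf((x - mu) / sigma)
    p = np.clip(p, 1e-9, 1.0 - 1e-9)
    return -np.sum(k * np.log(p) + (n - k) * np.log(1.0 - p))


def fit_psychometric(x: np.ndarray, k: np.ndarray, n: np.ndarray | int) -> PsychometricFit:
    """Maximum-likelihood cumulative Gaussian with symmetric guess/lapse.

    ``k`` successes out of ``n`` trials at each of >= 4 stimulus levels.
    The threshold (PSE) is the 50% point mu; the JND is sigma and
    sensitivity its reciprocal.  A fit pinned at the sigma lower bound
    (a step function) or with no identifiable slope is flagged degenerate.
    """
    x = np.asarray(x, dtype=float)
    k = np.asarray(k, dtype=float)
    n = np.broadcast_to(np.asarray(n, dtype=float), x.shape)
    if len(x) < 4:
        raise ValueError("need at least 4 stimulus levels")
    if np.allclose(k / n, (k / n)[0]):
        return PsychometricFit(float("nan"), float("inf"), 0.0, 0.0, len(x), degenerate=True)
    dx = np.ptp(x)
    lo_sigma = np.log(dx / 1e3)
    best = None
    for mu0 in (np.median(x), x[np.argmin(np.abs(k / n - 0.5))]):
        for s0 in (dx / 4.0, dx / 10.0):
            res = optimize.minimize(
                _psy_nll,
                [mu0, np.log(s0), 0.01],
                args=(x, k, n),
                method="L-BFGS-B",
                bounds=[(x.min() - dx, x.max() + dx), (lo_sigma, np.log(10 * dx)), (0.0, 0.2)],
            )
            if best is None or res.fun < best.fun:
                best = res
    mu, log_sigma, lapse = best.x
    sigma = float(np.exp(log_sigma))
    degenerate = log_sigma <= lo_sigma + 1e-6
    return PsychometricFit(
        float(mu), sigma, float(lapse), 1.0 / sigma, len(x), degenerate=degenerate
    )


def run_direction_psychometrics(
    net: NetworkParams,
    base_direction: float,
    offsets: np.ndarray | None = None,
    reps: int = 10,
    speed: float = 3.8,
    rng: np.random.Generator | None = None,
) -> PsychometricFit:
    """Direction-discrimination psychometrics from repeated dot decodes.

    Dot stimuli at ``speed`` px/frame move at ``base_direction + offset``;
    each offset is decoded ``reps`` times with fresh dot placements and
    the proportion of counter-clockwise decodes (relative to base) is fit
    against offset.  Sensitivity = 1 / sigma of the fit.
    """
    rng = rng or np.random.default_rng(0)
    if offsets is None:
        offsets = np.linspace(-20.0, 20.0, 10)
    spec = DotMotionSpec()
    k = np.zeros(len(offsets))
    for i, off in enumerate(offsets):
        for _ in range(reps):
            seq = make_dot_stimulus(spec, Velocity(base_direction + off, speed), rng)
            est = decode_direction(net, seq)
            if circdiff(est, base_direction) > 0:  # counter-clockwise
                k[i] += 1
    return fit_psychometric(np.asarray(offsets), k, reps)


def direction_sensitivity(
    net: NetworkParams,
    directions,
    reps: int = 10,
    rng: np.random.Generator | None = None,
) -> float:
    """Mean sensitivity over a set of base directions (cardinal or oblique)."""
    rng = rng or np.random.default_rng(0)
    vals = [run_direction_psychometrics(net, d, reps=reps, rng=rng).sensitivity for d in directions]
    return float(np.mean(vals))
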