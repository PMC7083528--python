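"""Neurophysiology-style characterisation of a trained network.

Mirrors the standard single-unit protocols: grating tuning maps for the
convolutional ("V1") units, dot-kinematogram direction tuning for the
readout ("MT") units, pattern/component classification with plaids and
partial correlations, motion-opponency probes, readout-weight alignment,
and the image-statistics computations (inter-direction image similarity
and the speed/spatiotemporal-contrast association) that the network's
learned structure is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    CARDINAL_DIRECTIONS,
    TRAINED_DIRECTIONS,
    TRAINED_SPEEDS,
    ImageSequence,
    Velocity,
    circdiff,
)
from .corpus import (
    TextureConfig,
    generate_texture,
    spatiotemporal_contrast,
    translate_sequence,
)
from .network import NetworkParams, forward_batch, mt_response, v1_response
from .decoding import (
    TuningFitParams,
    decode_direction_from_response,
    decode_speed_from_response,
    fit_von_mises,
)
from .stimuli import (
    DotMotionSpec,
    GratingSpec,
    PlaidSpec,
    RhombusSpec,
    make_dot_stimulus,
    make_grating,
    make_plaid,
    make_rhombus,
    unikinetic_plaid,
    contrast_ratio_series,
    speed_ratio_series,
)

SF_GRID = 2.0 ** np.linspace(1, 6, 8)  # px/cycle, log-spaced 2..64
TF_PERIODS = 2.0 ** np.linspace(1, 6, 8)  # frames/cycle, log-spaced 2..64


# ---------------------------------------------------------------------------
# V1 tuning maps and anisotropy census


def _phase_batch(direction: float, sf: float, speed: float, n_phases: int = 32) -> np.ndarray:
    phases = np.linspace(0.0, 360.0, n_phases, endpoint=False)
    return np.stack(
        [
            make_grating(GratingSpec(spatial_frequency=sf, direction=direction, speed=speed, phase=ph)).pixels
            for ph in phases
        ]
    )


def map_unit_tuning(
    net: NetworkParams,
    n_phases: int = 32,
    sf_grid: np.ndarray | None = None,
    tf_periods: np.ndarray | None = None,
) -> pd.DataFrame:
    """Grating tuning of every V1 unit over 8 x 8 x 8 stimulus types.

    Drifting sinusoids at the 8 trained directions, 8 log-spaced spatial
    frequencies (2-64 px/cycle) and 8 log-spaced temporal periods (2-64
    frames/cycle; drift speed = SF / period), each averaged over
    ``n_phases`` evenly spaced start phases.  A unit's preferences are
    read off the argmax of its mean response.  Coarser SF/TF grids can
    be supplied for quick direction censuses.
    """
    sf_grid = SF_GRID if sf_grid is None else np.asarray(sf_grid)
    tf_periods = TF_PERIODS if tf_periods is None else np.asarray(tf_periods)
    K = net.arch.n_kernels
    resp = np.zeros((8, len(sf_grid), len(tf_periods), K))
    for i_d, d in enumerate(TRAINED_DIRECTIONS):
        for i_s, sf in enumerate(sf_grid):
            for i_t, period in enumerate(tf_periods):
                batch = _phase_batch(d, sf, sf / period, n_phases)
                resp[i_d, i_s, i_t] = v1_response(net, batch).mean(axis=0)
    records = []
    for k in range(K):
        flat = int(np.argmax(resp[:, :, :, k]))
        i_d, i_s, i_t = np.unravel_index(flat, resp.shape[:3])
        records.append(
            {
                "unit": k,
                "pref_direction": TRAINED_DIRECTIONS[i_d],
                "pref_sf": sf_grid[i_s],
                "pref_tf": 1.0 / tf_periods[i_t],
                "pref_speed": sf_grid[i_s] / tf_periods[i_t],
                "is_cardinal": TRAINED_DIRECTIONS[i_d] % 90.0 == 0.0,
                "peak_response": resp[i_d, i_s, i_t, k],
            }
        )
    df = pd.DataFrame.from_records(records)
    df.attrs["responses"] = resp
    return df


def anisotropy_census(records: Iterable[pd.DataFrame]) -> dict:
    """Cardinal vs oblique V1 direction-preference proportions.

    ``records`` holds one tuning table per replicate network; the census
    returns per-replicate proportions plus their mean and SD.
    """
    props = np.array([df["is_cardinal"].mean() for df in records])
    if props.size == 0:
        raise ValueError("need at least one replicate")
    return {
        "cardinal_proportion": props,
        "mean_cardinal": float(props.mean()),
        "mean_oblique": float(1.0 - props.mean()),
        "sd_cardinal": float(props.std(ddof=1)) if props.size > 1 else 0.0,
    }


# ---------------------------------------------------------------------------
# MT direction tuning with dot kinematograms


def mt_dot_responses(
    net: NetworkParams,
    rng: np.random.Generator,
    n_directions: int = 16,
    n_reps: int = 8,
) -> np.ndarray:
    """Mean MT response (n_directions, 8 speeds, 64) to dot kinematograms."""
    spec = DotMotionSpec()
    dirs = np.arange(n_directions) * (360.0 / n_directions)
    out = np.zeros((n_directions, 8, 64))
    for i_d, d in enumerate(dirs):
        for i_s, s in enumerate(TRAINED_SPEEDS):
            batch = np.stack(
                [make_dot_stimulus(spec, Velocity(d, s), rng).pixels for _ in range(n_reps)]
            )
            out[i_d, i_s] = mt_response(net, batch).mean(axis=0)
    return out


def mt_direction_tuning(
    net: NetworkParams,
    rng: np.random.Generator | None = None,
    n_reps: int = 8,
    responses: np.ndarray | None = None,
) -> pd.DataFrame:
    """Aligned mean direction-tuning curve and width per preferred speed.

    For each speed, the 16-point direction response of each of the 8 MT
    units tuned to that speed is circularly shifted so its preferred
    direction sits at 0, then averaged; the width is the sigma of a von
    Mises fit to the average curve.
    """
    if responses is None:
        rng = rng or np.random.default_rng(0)
        responses = mt_dot_responses(net, rng, 16, n_reps)
    n_dir = responses.shape[0]
    step = 360.0 / n_dir
    offsets = np.arange(n_dir) * step
    rows = []
    for i_s in range(8):
        aligned = []
        for i_d in range(8):
            unit = 8 * i_d + i_s
            curve = responses[:, i_s, unit]
            shift = int(round(TRAINED_DIRECTIONS[i_d] / step))
            aligned.append(np.roll(curve, -shift))
        mean_curve = np.mean(aligned, axis=0)
        fit = fit_von_mises(offsets, mean_curve)
        rows.append(
            {
                "speed": TRAINED_SPEEDS[i_s],
                "width_sigma": fit.sigma,
                "curve": mean_curve,
                "offsets": offsets,
            }
        )
    return pd.DataFrame.from_records(rows)


def tuning_width_speed_correlation(tuning: pd.DataFrame) -> tuple[float, float]:
    """Pearson rho between log tuning width and preferred speed."""
    ok = np.isfinite(tuning["width_sigma"])
    rho, p = stats.pearsonr(np.log(tuning["width_sigma"][ok]), tuning["speed"][ok])
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# pattern vs component classification


@dataclass
class PatternComponentResult:
    unit: int
    layer: str
    r_p: float
    r_c: float
    r_cp: float
    R_p: float
    R_c: float
    Z_p: float
    Z_c: float
    label: str  # "component" | "pattern" | "unclassed"


def partial_correlations(data: np.ndarray, pattern: np.ndarray, component: np.ndarray):
    """Partial pattern/component correlations of a 16-direction response."""
    def _corr(a, b):
        if np.std(a) == 0 or np.std(b) == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    r_p = _corr(data, pattern)
    r_c = _corr(data, component)
    r_cp = _corr(pattern, component)
    denom_p = np.sqrt(max((1 - r_c**2) * (1 - r_cp**2), 1e-12))
    denom_c = np.sqrt(max((1 - r_p**2) * (1 - r_cp**2), 1e-12))
    R_p = (r_p - r_c * r_cp) / denom_p
    R_c = (r_c - r_p * r_cp) / denom_c
    return r_p, r_c, r_cp, float(R_p), float(R_c)


def _fisher_z(r: float, n: int) -> float:
    r = np.clip(r, -0.999999, 0.999999)
    return float(np.arctanh(r) * np.sqrt(n - 3))


def _pattern_component_label(R_p: float, R_c: float, n: int, crit: float = 1.645) -> tuple[str, float, float]:
    """Label from partial correlations via one-sided Fisher z tests."""
    Z_p, Z_c = _fisher_z(R_p, n), _fisher_z(R_c, n)
    if Z_c - max(Z_p, 0.0) > crit:
        return "component", Z_p, Z_c
    if Z_p - max(Z_c, 0.0) > crit:
        return "pattern", Z_p, Z_c
    return "unclassed", Z_p, Z_c


def _classify_from_curves(
    grating: np.ndarray, plaid: np.ndarray, separation: float, unit: int, layer: str
) -> PatternComponentResult:
    n = len(grating)
    step = 360.0 / n
    shift = int(round(separation / 2.0 / step))
    pattern_pred = grating.copy()
    component_pred = 0.5 * (np.roll(grating, shift) + np.roll(grating, -shift))
    if np.std(plaid) == 0:
        return PatternComponentResult(unit, layer, 0, 0, 0, 0, 0, 0, 0, "unclassed")
    r_p, r_c, r_cp, R_p, R_c = partial_correlations(plaid, pattern_pred, component_pred)
    label, Z_p, Z_c = _pattern_component_label(R_p, R_c, n)
    return PatternComponentResult(unit, layer, r_p, r_c, r_cp, R_p, R_c, Z_p, Z_c, label)


def classify_pattern_component(
    net: NetworkParams,
    layer: Literal["MT", "V1"] = "MT",
    separation: float = 90.0,
    tuning: pd.DataFrame | None = None,
    n_phases: int = 8,
) -> pd.DataFrame:
    """Component/pattern/unclassed labels for every unit of one layer.

    Responses to gratings and plaids (component separation
    ``separation``) drifting in 16 directions at each unit's preferred
    speed, averaged over start phases.  The ideal pattern prediction is
    the unit's own grating tuning; the ideal component prediction is the
    mean of that tuning shifted by +-separation/2.
    """
    dirs16 = np.arange(16) * 22.5
    phases = np.linspace(0.0, 360.0, n_phases, endpoint=False)
    results = []
    if layer == "MT":
        for i_s, speed in enumerate(TRAINED_SPEEDS):
            g_resp = np.zeros((16, 64))
            p_resp = np.zeros((16, 64))
            for i_d, d in enumerate(dirs16):
                gb = np.stack(
                    [
                        make_grating(GratingSpec(direction=d, speed=speed, phase=ph)).pixels
                        for ph in phases
                    ]
                )
                pb = np.stack(
                    [
                        make_plaid(
                            PlaidSpec(
                                direction=d,
                                separation=separation,
                                speeds=(speed, speed),
                                contrasts=(0.5, 0.5),
                                phases=(ph, -ph),
                            )
                        ).pixels
                        for ph in phases
                    ]
                )
                g_resp[i_d] = mt_response(net, gb).mean(axis=0)
                p_resp[i_d] = mt_response(net, pb).mean(axis=0)
            for i_d in range(8):
                unit = 8 * i_d + i_s
                results.append(
                    _classify_from_curves(g_resp[:, unit], p_resp[:, unit], separation, unit, "MT")
                )
    else:
        if tuning is None:
            tuning = map_unit_tuning(net, n_phases=8)
        for k in range(net.arch.n_kernels):
            sf = tuning.loc[k, "pref_sf"]
            speed = tuning.loc[k, "pref_speed"]
            g_curve = np.zeros(16)
            p_curve = np.zeros(16)
            for i_d, d in enumerate(dirs16):
                gb = np.stack(
                    [
                        make_grating(
                            GratingSpec(spatial_frequency=sf, direction=d, speed=speed, phase=ph)
                        ).pixels
                        for ph in phases
                    ]
                )
                pb = np.stack(
                    [
                        make_plaid(
                            PlaidSpec(
                                direction=d,
                                separation=separation,
                                speeds=(speed, speed),
                                contrasts=(0.5, 0.5),
                                spatial_frequency=sf,
                                phases=(ph, -ph),
                            )
                        ).pixels
                        for ph in phases
                    ]
                )
                g_curve[i_d] = v1_response(net, gb).mean(axis=0)[k]
                p_curve[i_d] = v1_response(net, pb).mean(axis=0)[k]
            results.append(_classify_from_curves(g_curve, p_curve, separation, k, "V1"))
    return pd.DataFrame([vars(r) for r in results])


# ---------------------------------------------------------------------------
# readout weight alignment


def kernel_direction_weights(net: NetworkParams) -> np.ndarray:
    """(K, 8) readout weights per V1 kernel by MT direction.

    Readout weights are averaged over spatial positions, then across the
    8 speeds within each direction column.
    """
    arch = net.arch
    K, p = arch.n_kernels, arch.pooled_size
    W = net.readout.reshape(K, p * p, 64).mean(axis=1)  # (K, 64)
    return W.reshape(K, 8, 8).mean(axis=2)  # average across speeds


def align_readout_weights(
    net: NetworkParams,
    mode: Literal["by_v1_preference", "by_max_weight", "by_min_weight"] = "by_v1_preference",
    tuning: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Mean V1-to-MT weight profile over direction offset (-180..135).

    Each kernel's 8-direction weight profile is circularly shifted so the
    alignment direction (the kernel's preferred grating direction, or its
    largest/smallest weight) sits at offset 0, then averaged over kernels.
    """
    Wd = kernel_direction_weights(net)
    K = Wd.shape[0]
    if mode == "by_v1_preference":
        if tuning is None:
            tuning = map_unit_tuning(net, n_phases=8)
        shifts = np.round(tuning["pref_direction"].to_numpy() / 45.0).astype(int) % 8
    elif mode == "by_max_weight":
        shifts = np.argmax(Wd, axis=1)
    elif mode == "by_min_weight":
        shifts = np.argmin(Wd, axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    aligned = np.stack([np.roll(Wd[k], -shifts[k]) for k in range(K)])
    profile = aligned.mean(axis=0)
    offsets = ((np.arange(8) * 45.0 + 180.0) % 360.0) - 180.0  # 0,45,..,-45
    order = np.argsort(offsets)
    return pd.DataFrame({"offset": offsets[order], "weight": profile[order]})


# ---------------------------------------------------------------------------
# motion opponency


def opponency_experiment(
    net: NetworkParams,
    tuning: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
    n_reps: int = 10,
) -> dict:
    """Opponent-dot suppression profiles and their relation to speed.

    12-dot kinematograms: 8 dots at a unit's preferred velocity, 4 at a
    distractor direction (same speed).  Responses are normalised to the
    coherent (offset 0) condition and symmetric offsets averaged; each
    unit's maximal-suppression offset is where its folded profile is
    minimal.  Pearson correlations between preferred speed and that
    offset are returned for MT (n = 64) and V1 (n = n_kernels).
    """
    rng = rng or np.random.default_rng(0)
    spec = DotMotionSpec(coherent_fraction=8 / 12, distractor_direction=0.0)
    offsets8 = TRAINED_DIRECTIONS  # distractor offsets 0..315
    fold = np.array([0.0, 45.0, 90.0, 135.0, 180.0])

    # responses[(i_dir, i_speed, i_offset)] for every probe direction/speed
    mt_resp = np.zeros((8, 8, 8, 64))
    v1_resp = np.zeros((8, 8, 8, net.arch.n_kernels))
    for i_d, d in enumerate(TRAINED_DIRECTIONS):
        for i_s, s in enumerate(TRAINED_SPEEDS):
            for i_o, off in enumerate(offsets8):
                sp = DotMotionSpec(coherent_fraction=8 / 12, distractor_direction=d + off)
                batch = np.stack(
                    [make_dot_stimulus(sp, Velocity(d, s), rng).pixels for _ in range(n_reps)]
                )
                A, _, probs = forward_batch(net, batch)
                mt_resp[i_d, i_s, i_o] = probs.mean(axis=0)
                v1_resp[i_d, i_s, i_o] = A.mean(axis=(0, 1, 2))

    def _fold_profile(prof8: np.ndarray) -> np.ndarray:
        folded = np.empty(5)
        folded[0] = prof8[0]
        folded[4] = prof8[4]
        for j in (1, 2, 3):
            folded[j] = 0.5 * (prof8[j] + prof8[8 - j])
        return folded

    def _min_offset(folded: np.ndarray) -> float:
        # parabolic interpolation around the sampled minimum for a
        # continuous suppression offset
        i = int(np.argmin(folded))
        if 0 < i < len(folded) - 1:
            a, b, c = folded[i - 1], folded[i], folded[i + 1]
            denom = a - 2.0 * b + c
            if denom > 0:
                return float(fold[i] + np.clip(0.5 * (a - c) / denom, -1, 1) * 45.0)
        return float(fold[i])

    # MT: each unit probed at its own labelled velocity
    mt_rows = []
    for i_d in range(8):
        for i_s in range(8):
            unit = 8 * i_d + i_s
            prof = mt_resp[i_d, i_s, :, unit]
            if prof[0] <= 0:
                continue
            folded = _fold_profile(prof / prof[0])
            mt_rows.append(
                {
                    "unit": unit,
                    "speed": TRAINED_SPEEDS[i_s],
                    "profile": folded,
                    "suppression_offset": _min_offset(folded),
                }
            )
    mt_df = pd.DataFrame(mt_rows)
    rho_mt, p_mt = stats.pearsonr(mt_df["speed"], mt_df["suppression_offset"])

    # V1: each kernel probed at its preferred grating direction and speed
    if tuning is None:
        tuning = map_unit_tuning(net, n_phases=8)
    v1_rows = []
    for k in range(net.arch.n_kernels):
        i_d = int(round(tuning.loc[k, "pref_direction"] / 45.0)) % 8
        i_s = int(np.argmin(np.abs(TRAINED_SPEEDS - tuning.loc[k, "pref_speed"])))
        prof = v1_resp[i_d, i_s, :, k]
        if prof[0] <= 0:
            continue
        folded = _fold_profile(prof / prof[0])
        v1_rows.append(
            {
                "unit": k,
                "speed": TRAINED_SPEEDS[i_s],
                "profile": folded,
                "suppression_offset": _min_offset(folded),
            }
        )
    v1_df = pd.DataFrame(v1_rows)
    if v1_df["speed"].nunique() > 1 and v1_df["suppression_offset"].nunique() > 1:
        rho_v1, p_v1 = stats.pearsonr(v1_df["speed"], v1_df["suppression_offset"])
    else:
        rho_v1, p_v1 = float("nan"), float("nan")
    return {
        "mt": mt_df,
        "v1": v1_df,
        "rho_mt": float(rho_mt),
        "p_mt": float(p_mt),
        "rho_v1": float(rho_v1),
        "p_v1": float(p_v1),
        "offsets": fold,
    }


# ---------------------------------------------------------------------------
# IOC and vector average


def ioc_velocity(c1: Velocity, c2: Velocity) -> Velocity:
    """Intersection-of-constraints solution for two motion components.

    Each component constrains the true velocity to the line
    v . u_i = speed_i with u_i the component's unit direction vector; the
    IOC is the unique intersection of the two lines.
    """
    th1, th2 = np.deg2rad(c1.direction), np.deg2rad(c2.direction)
    M = np.array([[np.cos(th1), np.sin(th1)], [np.cos(th2), np.sin(th2)]])
    if abs(np.linalg.det(M)) < 1e-10:
        if abs(circdiff(c1.direction, c2.direction)) < 1e-9 and abs(c1.speed - c2.speed) < 1e-9:
            return c1  # coincident constraints: the component itself
        raise np.linalg.LinAlgError("parallel constraint lines: IOC undefined")
    ix, iy = np.linalg.solve(M, [c1.speed, c2.speed])
    return Velocity(np.rad2deg(np.arctan2(iy, ix)), float(np.hypot(ix, iy)))


def va_velocity(c1: Velocity, c2: Velocity) -> Velocity:
    """Vector-average solution: the mean of the component vectors."""
    x = (c1.cartesian[0] + c2.cartesian[0]) / 2.0
    y = (c1.cartesian[1] + c2.cartesian[1]) / 2.0
    return Velocity(np.rad2deg(np.arctan2(y, x)), float(np.hypot(x, y)))


def rhombus_components(spec: RhombusSpec) -> tuple[Velocity, Velocity]:
    """Edge-normal motion components of a translating rhombus.

    Each edge only signals the velocity component along its outward
    normal (the aperture problem); the IOC of the two components is the
    rhombus's true velocity, their vector average generally is not.
    """
    v = Velocity(spec.direction, spec.speed)
    vx, vy = v.cartesian
    comps = []
    for n_vec in spec.edge_normals():
        s = vx * n_vec[0] + vy * n_vec[1]
        if s < 0:
            n_vec, s = -n_vec, -s
        comps.append(Velocity(np.rad2deg(np.arctan2(n_vec[1], n_vec[0])), float(s)))
    return tuple(comps)


# ---------------------------------------------------------------------------
# direction experiments


def _phase_averaged_mt(net: NetworkParams, make_seq, n_phases: int = 8) -> np.ndarray:
    phases = np.linspace(0.0, 360.0, n_phases, endpoint=False)
    batch = np.stack([make_seq(ph).pixels for ph in phases])
    return mt_response(net, batch).mean(axis=0)


def _aligned_mt(net: NetworkParams, make_seq, n_phases: int = 4) -> np.ndarray:
    """Population response averaged over the 8 trained directions.

    ``make_seq(direction, phase)`` must return the stimulus rotated so
    its nominal direction is ``direction``.  Responses are rotated back
    onto a common 0-degree axis before averaging, cancelling any
    direction anisotropy of the network itself; the returned (64,)
    vector is expressed relative to the stimulus direction.
    """
    phases = np.linspace(0.0, 360.0, n_phases, endpoint=False)
    acc = np.zeros((8, 8))
    for i_d, d in enumerate(TRAINED_DIRECTIONS):
        batch = np.stack([make_seq(d, ph).pixels for ph in phases])
        mean = mt_response(net, batch).mean(axis=0).reshape(8, 8)
        acc += np.roll(mean, -i_d, axis=0)
    return (acc / 8.0).ravel()


def plaid_speed_ratio_experiment(net: NetworkParams, base_speed: float = 0.8) -> pd.DataFrame:
    """Decoded plaid velocity vs component speed ratio, with IOC/VA refs."""
    ratios = np.linspace(0.5, 2.0, 16)
    rows = []
    for r in ratios:
        speeds = (base_speed, base_speed * r)
        mt = _aligned_mt(
            net,
            lambda d, ph, sp=speeds: make_plaid(
                PlaidSpec(d, 90.0, sp, phases=(ph, -ph))
            ),
            n_phases=8,
        )
        est_dir, _ = decode_direction_from_response(mt)
        est_speed, _ = decode_speed_from_response(mt)
        c1 = Velocity(45.0, base_speed)
        c2 = Velocity(-45.0, base_speed * r)
        ioc = ioc_velocity(c1, c2)
        va = va_velocity(c1, c2)
        rows.append(
            {
                "ratio": r,
                "decoded_direction": est_dir,
                "decoded_speed": est_speed,
                "ioc_direction": ioc.direction,
                "ioc_speed": ioc.speed,
                "va_direction": va.direction,
                "va_speed": va.speed,
            }
        )
    return pd.DataFrame(rows)


def unikinetic_experiment(net: NetworkParams, n_steps: int = 20) -> pd.DataFrame:
    """Decoded direction of one-static-component plaids vs separation.

    Bias is the signed angular deviation of the decode from the moving
    component's direction; positive values rotate toward the static
    component's drift axis (and hence toward its orientation).
    """
    seps = np.linspace(0.0, 45.0, n_steps)
    rows = []
    for sep in seps:
        mt = _aligned_mt(
            net,
            lambda d, ph, s=sep: unikinetic_plaid(s, moving_speed=3.8, direction=d, phases=(ph, -ph)),
        )
        est, _ = decode_direction_from_response(mt)
        rows.append(
            {
                "separation": sep,
                "decoded_direction": est,
                "bias": circdiff(est, 0.0),
                "degenerate": sep == 0.0,
            }
        )
    return pd.DataFrame(rows)


def contrast_ratio_experiment(net: NetworkParams) -> pd.DataFrame:
    """Direction bias toward the higher-contrast plaid component.

    The pattern direction is 0; component 1 (the higher-contrast one at
    positive log contrast ratios) drifts at +45.  Bias is the signed
    decode deviation from the pattern direction, positive toward
    component 1.
    """
    rows = []
    for spec in contrast_ratio_series():
        mt = _aligned_mt(
            net,
            lambda d, ph, s=spec: make_plaid(
                PlaidSpec(d, s.separation, s.speeds, s.contrasts, s.spatial_frequency, (ph, -ph))
            ),
        )
        est, _ = decode_direction_from_response(mt)
        rows.append(
            {
                "total_contrast": sum(spec.contrasts),
                "log_contrast_ratio": float(np.log10(spec.contrasts[0] / spec.contrasts[1])),
                "decoded_direction": est,
                "bias_toward_stronger": circdiff(est, 0.0),
            }
        )
    return pd.DataFrame(rows)


def rhombus_experiment(
    net: NetworkParams,
    aspect_ratios: Sequence[float] = (0.1, 0.8),
    contrasts: np.ndarray | None = None,
) -> pd.DataFrame:
    """Decoded rhombus direction vs contrast with IOC and VA references."""
    if contrasts is None:
        contrasts = np.logspace(np.log10(0.2), np.log10(1.0), 8)
    rows = []
    for ar in aspect_ratios:
        ref = RhombusSpec(aspect_ratio=ar, contrast=1.0)
        c1, c2 = rhombus_components(ref)
        ioc = ioc_velocity(c1, c2)
        va = va_velocity(c1, c2)
        for c in contrasts:
            mt = _aligned_mt(
                net,
                lambda d, ph, cc=float(c): make_rhombus(
                    RhombusSpec(
                        aspect_ratio=ar,
                        contrast=cc,
                        direction=d,
                        orientation=RhombusSpec.__dataclass_fields__["orientation"].default - d,
                    )
                ),
                n_phases=1,
            )
            est, _ = decode_direction_from_response(mt)
            rows.append(
                {
                    "aspect_ratio": ar,
                    "contrast": float(c),
                    "decoded_direction": est,
                    "ioc_direction": ioc.direction,
                    "va_direction": va.direction,
                    "dist_to_ioc": abs(circdiff(est, ioc.direction)),
                    "dist_to_va": abs(circdiff(est, va.direction)),
                }
            )
    return pd.DataFrame(rows)


def motion_step_experiment(net: NetworkParams, max_steps: int = 6) -> pd.DataFrame:
    """Grating that starts static and moves for the first k frame steps."""
    rows = []
    for k_steps in range(max_steps + 1):
        def seq_for(ph):
            g = make_grating(GratingSpec(direction=0.0, speed=0.8, phase=ph)).pixels
            out = g.copy()
            for t in range(1, g.shape[2]):
                if t > k_steps:
                    out[:, :, t] = out[:, :, k_steps]
            return ImageSequence(out)

        mt = _phase_averaged_mt(net, seq_for)
        est, fit = decode_direction_from_response(mt)
        rows.append(
            {
                "motion_steps": k_steps,
                "decoded_direction": est,
                "peak_response": float(mt.max()),
                "fit_fallback": fit.fallback,
            }
        )
    return pd.DataFrame(rows)


def grating_speed_vs_contrast(
    net: NetworkParams,
    contrasts: Sequence[float] | None = None,
    speed: float = 2.5,
) -> pd.DataFrame:
    """Decoded grating speed at low contrast relative to full contrast.

    ``relative_matching_speed`` below 1 reproduces the classic
    slower-at-low-contrast misperception.
    """
    if contrasts is None:
        contrasts = 0.002 * 2.0 ** np.arange(5)  # log2-spaced 0.002..0.032
    full = _phase_averaged_mt(
        net, lambda ph: make_grating(GratingSpec(direction=0.0, speed=speed, phase=ph, contrast=1.0))
    )
    full_speed, _ = decode_speed_from_response(full)
    rows = []
    for c in contrasts:
        mt = _phase_averaged_mt(
            net,
            lambda ph, cc=c: make_grating(
                GratingSpec(direction=0.0, speed=speed, phase=ph, contrast=float(cc))
            ),
        )
        est, _ = decode_speed_from_response(mt)
        rows.append(
            {
                "contrast": float(c),
                "decoded_speed": est,
                "full_contrast_speed": full_speed,
                "relative_matching_speed": est / full_speed,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# offset parameters and the slow-speed bias


def offset_bias_analysis(net: NetworkParams) -> dict:
    """Relation of learned offsets to speed tuning.

    ``rho_mt``: Pearson correlation over the 8 speeds between preferred
    speed and the MT offset parameter averaged across directions.
    ``t_v1``: two-sample t statistic comparing conv offsets of V1 units
    whose largest-|weight| readout connection targets a slow- vs a
    fast-preferring MT unit, restricted to the top 50% most influential
    units by absolute weight.
    """
    b_mt = net.readout_offsets.reshape(8, 8)  # (direction, speed)
    mean_offsets = b_mt.mean(axis=0)
    if np.allclose(mean_offsets, mean_offsets[0]):
        return {"rho_mt": float("nan"), "p_mt": float("nan"), "degenerate": True}
    rho_mt, p_mt = stats.pearsonr(mean_offsets, TRAINED_SPEEDS)

    arch = net.arch
    K, p = arch.n_kernels, arch.pooled_size
    Wk = net.readout.reshape(K, p * p, 64).mean(axis=1)  # (K, 64) mean weight
    target = np.argmax(np.abs(Wk), axis=1)
    influence = np.max(np.abs(Wk), axis=1)
    top = influence >= np.median(influence)
    slow = (target % 8) < 4
    b_v1 = net.conv_offsets
    grp_slow = b_v1[top & slow]
    grp_fast = b_v1[top & ~slow]
    if len(grp_slow) > 1 and len(grp_fast) > 1:
        t_v1, p_v1 = stats.ttest_ind(grp_slow, grp_fast)
    else:
        t_v1, p_v1 = float("nan"), float("nan")
    return {
        "rho_mt": float(rho_mt),
        "p_mt": float(p_mt),
        "mean_mt_offsets": mean_offsets,
        "t_v1": float(t_v1),
        "p_v1": float(p_v1),
        "n_slow": int(len(grp_slow)),
        "n_fast": int(len(grp_fast)),
        "degenerate": False,
    }


# ---------------------------------------------------------------------------
# image statistics


def image_similarity_analysis(
    cfg: TextureConfig | None = None,
    rng: np.random.Generator | None = None,
    n_sources: int = 100,
    offsets: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean Pearson similarity between a sequence and its rotated twins.

    Each source texture is translated at direction 0 and at direction
    offsets up to 180 degrees, at every trained speed; similarity is the
    Pearson correlation between the two sequences' pixels, averaged over
    sources.  Returns a tidy frame (offset, speed, similarity).
    """
    cfg = cfg or TextureConfig()
    rng = rng or np.random.default_rng(0)
    if offsets is None:
        offsets = np.arange(0.0, 180.1, 22.5)
    sims = np.zeros((len(offsets), 8))
    for _ in range(n_sources):
        tex = generate_texture(cfg, rng)
        src = tex.pixels[:, :, 0]
        for i_s, speed in enumerate(TRAINED_SPEEDS):
            base = translate_sequence(src, Velocity(0.0, speed)).pixels.ravel()
            base = base - base.mean()
            nb = np.linalg.norm(base)
            for i_o, off in enumerate(offsets):
                other = translate_sequence(src, Velocity(off, speed)).pixels.ravel()
                other = other - other.mean()
                denom = nb * np.linalg.norm(other)
                sims[i_o, i_s] += float(base @ other / denom) if denom > 0 else 0.0
    sims /= n_sources
    rows = [
        {"offset": offsets[i_o], "speed": TRAINED_SPEEDS[i_s], "similarity": sims[i_o, i_s]}
        for i_o in range(len(offsets))
        for i_s in range(8)
    ]
    df = pd.DataFrame(rows)
    df.attrs["matrix"] = sims
    return df


def similarity_mt_correlation(
    similarity: pd.DataFrame, tuning: pd.DataFrame
) -> tuple[float, float]:
    """Correlate image similarity with normalised MT tuning (n = 24).

    Near-preferred direction offsets (22.5, 45, 67.5 degrees) at each of
    the 8 speeds: the image-similarity value is paired with the aligned,
    max-normalised MT tuning response at the same offset and speed.
    """
    probe_offsets = (22.5, 45.0, 67.5)
    sim_vals, mt_vals = [], []
    for _, row in tuning.iterrows():
        curve = np.asarray(row["curve"], dtype=float)
        offs = np.asarray(row["offsets"], dtype=float)
        norm = curve / curve.max() if curve.max() > 0 else curve
        for po in probe_offsets:
            i_pos = int(np.argmin(np.abs(offs - po)))
            i_neg = int(np.argmin(np.abs(offs - (360.0 - po))))
            mt_vals.append(0.5 * (norm[i_pos] + norm[i_neg]))
            sim_sel = similarity[
                (np.isclose(similarity["offset"], po)) & (np.isclose(similarity["speed"], row["speed"]))
            ]
            sim_vals.append(float(sim_sel["similarity"].iloc[0]))
    rho, p = stats.pearsonr(sim_vals, mt_vals)
    return float(rho), float(p)


def speed_contrast_correlation(
    cfg: TextureConfig | None = None,
    rng: np.random.Generator | None = None,
    n: int = 5000,
    speed_range: tuple[float, float] = (1.0, 16.0),
    patch: int = 16,
) -> tuple[float, float]:
    """Pearson rho between random rightward speed and sequence contrast.

    Samples ``n`` sequences (``patch`` x ``patch`` x 6) from fresh
    textures translated rightward at uniformly random speeds.
    """
    rng = rng or np.random.default_rng(0)
    from dataclasses import replace

    min_size = patch + int(np.ceil(6 * speed_range[1])) + 2
    if cfg is None:
        cfg = TextureConfig(source_size=max(128, min_size))
    elif cfg.source_size < min_size:
        cfg = replace(cfg, source_size=max(128, min_size))
    speeds = rng.uniform(speed_range[0], speed_range[1], size=n)
    contrasts = np.empty(n)
    for i in range(n):
        tex = generate_texture(cfg, rng)
        seq = translate_sequence(tex.pixels[:, :, 0], Velocity(0.0, speeds[i]), patch=patch)
        contrasts[i] = spatiotemporal_contrast(seq)
    rho, p = stats.pearsonr(speeds, contrasts)
    return float(rho), float(p)
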