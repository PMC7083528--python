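"""Run configuration, persistence and end-to-end reproduction recipes.

A :class:`RunConfig` fully determines a run: corpus settings, network
and training settings, and the master seed.  Every artifact a recipe
writes carries the config hash and seed, so re-running with the same
config reproduces all numbers exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import analyses, priors
from .corpus import (
    DotWorldConfig,
    TextureConfig,
    TrainingSet,
    blur_or_sharpen,
    build_training_set,
    dot_sequence_generator,
    reverse_speed_contrast,
    texture_sequence_generator,
)
from .network import (
    Architecture,
    NetworkParams,
    TrainingConfig,
    scaled_architecture,
    scaled_training_config,
    train_fresh,
)

FIGURE_TAGS = ("fig2", "fig3", "fig4", "fig5", "fig6", "fig7")


@dataclass(frozen=True)
class RunConfig:
    """Serializable description of one training/analysis run."""

    corpus_kind: str = "texture"  # "texture" | "dots"
    n_per_class: int = 50
    corpus_variant: str = "standard"  # standard | reverse | blur | sharpen | slow | fast
    texture: TextureConfig = field(default_factory=TextureConfig)
    dots: DotWorldConfig = field(default_factory=DotWorldConfig)
    n_kernels: int = 32
    epochs: int = 200
    learning_rate: float = 0.25
    batch_size: int = 100
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @property
    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def build_corpus(cfg: RunConfig) -> TrainingSet:
    if cfg.corpus_kind == "texture":
        gen = texture_sequence_generator(cfg.texture)
    elif cfg.corpus_kind == "dots":
        gen = dot_sequence_generator(cfg.dots)
    else:
        raise ValueError(f"unknown corpus kind {cfg.corpus_kind!r}")
    world = cfg.corpus_variant if cfg.corpus_variant in ("slow", "fast") else "none"
    ts = build_training_set(gen, cfg.n_per_class, cfg.seed, speed_world=world)
    if cfg.corpus_variant == "reverse":
        ts = reverse_speed_contrast(ts)
    elif cfg.corpus_variant in ("blur", "sharpen"):
        ts = blur_or_sharpen(ts, cfg.corpus_variant)
    return ts


def run_training(cfg: RunConfig, ts: TrainingSet | None = None) -> NetworkParams:
    ts = ts if ts is not None else build_corpus(cfg)
    arch = scaled_architecture(cfg.n_kernels)
    tcfg = TrainingConfig(cfg.learning_rate, cfg.batch_size, cfg.epochs, cfg.seed)
    return train_fresh(ts, arch, tcfg)


def _write(outdir: Path, name: str, df: pd.DataFrame, cfg: RunConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    df = df.copy()
    df["config_hash"] = cfg.hash
    df["seed"] = cfg.seed
    df.to_csv(outdir / f"{name}.csv", index=False)


def _summary(outdir: Path, name: str, payload: dict, cfg: RunConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    payload = dict(payload, config_hash=cfg.hash, seed=cfg.seed, written=time.strftime("%Y-%m-%d"))
    (outdir / f"{name}.json").write_text(json.dumps(payload, indent=2, default=float))


def reproduce(tag: str, outdir: str | Path, seed: int = 0, n_per_class: int = 20, epochs: int = 100) -> dict:
    """Run a desk-scale recipe for one results figure and write artifacts.

    Recipes train small networks on demand; sizes are deliberately modest
    (they are meant for interactive reproduction, not for the full-scale
    statistics).  Returns the summary statistics dictionary.
    """
    outdir = Path(outdir)
    if tag == "fig7":
        cfg = RunConfig(seed=seed)
        df = priors.simulate_experiment(seed=seed)
        _write(outdir, "fig7_thresholds", df, cfg)
        summary = {
            row["model"] + "/" + row["condition"]: row["threshold"] for _, row in df.iterrows()
        }
        _summary(outdir, "fig7_summary", summary, cfg)
        return summary
    if tag == "fig2":
        summaries = {}
        frames = []
        for variant, kind, tex in (
            ("cardinal_textures", "texture", TextureConfig()),
            ("rotated_textures", "texture", TextureConfig(anisotropy_axis_deg=45.0)),
            ("isotropic_dots", "dots", None),
        ):
            cfg = RunConfig(
                corpus_kind=kind,
                texture=tex or TextureConfig(),
                n_per_class=n_per_class,
                epochs=epochs,
                seed=seed,
            )
            net = run_training(cfg)
            tuning = analyses.map_unit_tuning(net, n_phases=8)
            census = analyses.anisotropy_census([tuning])
            summaries[variant] = census["mean_cardinal"]
            tuning["variant"] = variant
            frames.append(tuning)
            _write(outdir, f"fig2_{variant}_tuning", tuning, cfg)
        _summary(outdir, "fig2_summary", summaries, RunConfig(seed=seed))
        return summaries
    if tag in ("fig3", "fig4", "fig5"):
        cfg = RunConfig(seed=seed, n_per_class=n_per_class, epochs=epochs)
        net = run_training(cfg)
        if tag == "fig3":
            pc = analyses.classify_pattern_component(net, "MT")
            _write(outdir, "fig3_pattern_component_mt", pc, cfg)
            weights = analyses.align_readout_weights(net, "by_max_weight")
            _write(outdir, "fig3_weights_by_max", weights, cfg)
            summary = dict(pc["label"].value_counts())
            _summary(outdir, "fig3_summary", {k: int(v) for k, v in summary.items()}, cfg)
            return summary
        if tag == "fig4":
            sr = analyses.plaid_speed_ratio_experiment(net)
            uk = analyses.unikinetic_experiment(net)
            cr = analyses.contrast_ratio_experiment(net)
            _write(outdir, "fig4_speed_ratio", sr, cfg)
            _write(outdir, "fig4_unikinetic", uk, cfg)
            _write(outdir, "fig4_contrast_ratio", cr, cfg)
            summary = {
                "max_ioc_deviation_deg": float(
                    np.max(np.abs(sr["decoded_direction"].apply(lambda d: (d + 180) % 360 - 180) - sr["ioc_direction"].apply(lambda d: (d + 180) % 360 - 180)))
                )
            }
            _summary(outdir, "fig4_summary", summary, cfg)
            return summary
        rng = np.random.default_rng(seed)
        opp = analyses.opponency_experiment(net, rng=rng, n_reps=4)
        rh = analyses.rhombus_experiment(net)
        sp = analyses.grating_speed_vs_contrast(net)
        _write(outdir, "fig5_rhombus", rh, cfg)
        _write(outdir, "fig5_speed_contrast_decode", sp, cfg)
        summary = {"rho_mt_opponency": opp["rho_mt"], "rho_v1_opponency": opp["rho_v1"]}
        _summary(outdir, "fig5_summary", summary, cfg)
        return summary
    if tag == "fig6":
        summaries = {}
        for variant in ("standard", "reverse", "blur", "sharpen", "slow", "fast"):
            cfg = RunConfig(
                corpus_variant=variant, n_per_class=n_per_class, epochs=epochs, seed=seed
            )
            net = run_training(cfg)
            res = analyses.offset_bias_analysis(net)
            summaries[variant] = res["rho_mt"]
            _write(
                outdir,
                f"fig6_{variant}_offsets",
                pd.DataFrame(
                    {"speed": np.linspace(0.8, 3.8, 8), "mean_offset": res["mean_mt_offsets"]}
                ),
                cfg,
            )
        _summary(outdir, "fig6_summary", summaries, RunConfig(seed=seed))
        return summaries
    raise ValueError(f"unknown figure tag {tag!r}; expected one of {FIGURE_TAGS}")
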