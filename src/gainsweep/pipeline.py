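"""Experiment recipes: reproducible end-to-end runs of the analyses.

A :class:`StudyConfig` fixes every knob of a study — stimulus geometry,
backbone shape, training lengths, gain grid, probe and scrambling
settings — and every stage seed is derived from its single base seed.
``run_experiment`` executes one of four recipes and writes tidy CSV
tables plus a JSON manifest (config snapshot, seeds, output checksums)
so a run can be audited and re-run bit-identically.

Recipes
-------
``yerkes_dodson``
    Train per-difficulty heads, sweep the gain grid, extract accuracy /
    sensitivity / criterion profiles and their peak gain states.
``answer_options``
    Category heads over answer-option subsets; AUC-vs-gain profiles.
``decoding``
    Block-wise logistic probes and mean activations across gain states
    and difficulties; peak-decoding gains and most-informative blocks.
``scrambling``
    Importance-curve calibration, then progressive late->early and
    early->late disruption under a gain sweep.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .activations import ActivationSpec
from .backbone import (BackboneConfig, BackboneModel, GainStateCache,
                       forward_with_taps, set_gain_state, set_global_gain)
from .images import (
    DifficultyLevel,
    LabeledDataset,
    StyleParams,
    build_difficulty_suite,
    generate_category_dataset,
    split_dataset,
)
from .metrics import summarize_ci
from .probe import decode_block, decoding_peak_gain, mean_activation, most_informative_block
from .scramble import (
    calibrate_rate,
    importance_curve,
    progressive_plans,
    progressive_scramble_sweep,
    stage_peaks,
)
from .sweep import GainGrid, find_peak, sweep, sweep_category
from .training import (
    HeadConfig,
    PretrainConfig,
    finetune_category_head,
    finetune_head,
    pretrain_backbone,
    subsample_answer_options,
)

RECIPES = ("yerkes_dodson", "answer_options", "decoding", "scrambling")


def stage_seed(base: int, name: str) -> int:
    """Deterministic per-stage seed derived from the base seed."""
    tag = zlib.crc32(name.encode())
    return int(np.random.SeedSequence([base, tag]).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class StudyConfig:
    """All parameters of one study; defaults are the full-scale setup."""

    seed: int = 0
    # stimuli
    image_size: int = 64
    levels: Tuple[float, ...] = (1.25, 2.0, 3.0, 6.0, 20.0, 40.0)
    n_per_split: Tuple[int, int, int] = (2000, 600, 600)
    # backbone
    stem_width: int = 16
    widths: Tuple[int, ...] = (16, 16, 32, 32, 64, 64, 128, 128)
    strides: Tuple[int, ...] = (1, 1, 2, 1, 2, 1, 2, 1)
    activation_kind: str = "saturating"
    a_max: float = 5.0
    norm: str = "batch"
    # pretraining task
    pretrain_categories: int = 8
    pretrain_per_category: int = 250
    pretrain_epochs: int = 15
    pretrain_lr: float = 0.05
    # heads
    n_instances: int = 10
    head_epochs: int = 15
    head_lr: float = 0.5
    # gain grid
    grid_lo: float = 0.125
    grid_hi: float = 8.0
    grid_n: int = 60
    # answer options
    option_sizes: Tuple[int, ...] = (2, 4, 8)
    option_iterations: int = 20
    # decoding probes
    probe_n_train: int = 1000
    probe_n_test: int = 1000
    probe_n_iter: int = 5
    probe_max_dim: int = 4096
    probe_grid_n: int = 7
    ceiling_threshold: float = 0.99
    calib_n: int = 512  # images used to recalibrate normalisation per gain state
    # scrambling
    scramble_reps: int = 10
    scramble_p_grid: Tuple[float, ...] = tuple(np.round(np.arange(0, 1.01, 0.1), 2))
    retention_threshold: float = 0.2
    scramble_grid_n: int = 15
    scramble_test_n: Optional[int] = None  # subsample of test images; None = all

    def gain_grid(self) -> GainGrid:
        return GainGrid.geometric(self.grid_lo, self.grid_hi, self.grid_n)

    def probe_grid(self) -> GainGrid:
        return GainGrid.geometric(self.grid_lo, self.grid_hi, self.probe_grid_n)

    def scramble_grid(self) -> GainGrid:
        return GainGrid.geometric(self.grid_lo, self.grid_hi, self.scramble_grid_n)

    def style(self) -> StyleParams:
        return StyleParams(image_size=self.image_size)

    def backbone_config(self) -> BackboneConfig:
        return BackboneConfig(
            image_size=self.image_size,
            stem_width=self.stem_width,
            widths=self.widths,
            strides=self.strides,
            n_classes=self.pretrain_categories,
            norm=self.norm,
            activation=ActivationSpec(kind=self.activation_kind, a_max=self.a_max),
        )

    def pretrain_config(self) -> PretrainConfig:
        return PretrainConfig(
            epochs=self.pretrain_epochs,
            lr=self.pretrain_lr,
            seed=stage_seed(self.seed, "pretrain"),
        )

    def head_config(self) -> HeadConfig:
        return HeadConfig(
            n_instances=self.n_instances,
            epochs=self.head_epochs,
            lr=self.head_lr,
            seed=stage_seed(self.seed, "heads"),
        )


def desk_profile(seed: int = 0, **overrides) -> StudyConfig:
    """Reduced problem sizes for single-CPU runs of the full pipeline.

    Same structure as the default study (8 residual blocks, shared
    backbone, balanced parametric-difficulty suites), with smaller
    images, narrower widths and fewer instances / grid points.
    """
    cfg = StudyConfig(
        seed=seed,
        image_size=32,
        levels=(1.25, 20.0),
        n_per_split=(600, 160, 400),
        pretrain_per_category=120,
        pretrain_epochs=14,
        n_instances=5,
        calib_n=256,
        grid_n=21,
        option_iterations=8,
        probe_n_train=300,
        probe_n_test=300,
        probe_n_iter=3,
        probe_max_dim=1024,
        scramble_reps=5,
        scramble_p_grid=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
        scramble_grid_n=13,
        scramble_test_n=160,
    )
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------- study

class Study:
    """Builds and caches the shared stages (stimuli, backbone, heads) of
    one configured study."""

    def __init__(self, config: StudyConfig, out_dir: Optional[Path] = None):
        self.config = config
        self.out_dir = Path(out_dir) if out_dir is not None else None
        if self.out_dir is not None:
            self.out_dir.mkdir(parents=True, exist_ok=True)
        self._suite = None
        self._backbone = None
        self._heads: Dict[float, list] = {}
        self._category_splits = None
        self._calib = None
        self.history: List[dict] = []

    # ----- stimuli
    def suite(self):
        if self._suite is None:
            self._suite = build_difficulty_suite(
                self.config.levels,
                n_per_split=self.config.n_per_split,
                seed=stage_seed(self.config.seed, "suite"),
                style_params=self.config.style(),
            )
        return self._suite

    def category_splits(self):
        if self._category_splits is None:
            data = generate_category_dataset(
                self.config.pretrain_categories,
                self.config.pretrain_per_category,
                seed=stage_seed(self.config.seed, "categories"),
                style_params=self.config.style(),
            )
            self._category_splits = split_dataset(
                data, seed=stage_seed(self.config.seed, "category-split")
            )
        return self._category_splits

    # ----- models
    def backbone(self) -> BackboneModel:
        if self._backbone is not None:
            return self._backbone
        ckpt = self.out_dir / "backbone.npz" if self.out_dir else None
        if ckpt is not None and ckpt.exists():
            self._backbone = BackboneModel.load(ckpt)
            return self._backbone
        model, history = pretrain_backbone(
            self.category_splits(),
            self.config.pretrain_config(),
            self.config.backbone_config(),
        )
        self.history = history
        if ckpt is not None:
            model.save(ckpt)
        self._backbone = model
        return model

    def heads(self, level: float):
        if level not in self._heads:
            self._heads[level] = finetune_head(
                self.backbone(),
                self.suite()[level],
                self.config.head_config(),
                condition=level,
                calib=self.calib(),
            )
        return self._heads[level]

    def calib(self, level: float = None) -> np.ndarray:
        """Normalisation-calibration images: the generic pretraining train
        split. One shared ambient distribution for every condition keeps
        the neutral state canonical and avoids adapting the model to any
        task's own statistics."""
        if self._calib is None:
            x = self.category_splits()["train"].as_nchw()
            n = self.config.calib_n
            if n is not None and n < len(x):
                rng = np.random.default_rng(stage_seed(self.config.seed, "calib"))
                x = x[rng.permutation(len(x))[:n]]
            self._calib = x
        return self._calib

    def test_set(self, level: float, n: Optional[int] = None) -> LabeledDataset:
        ds = self.suite()[level]["test"]
        if n is None or n >= len(ds):
            return ds
        rng = np.random.default_rng(stage_seed(self.config.seed, f"subset-{level}-{n}"))
        idx = rng.permutation(len(ds))[:n]
        return LabeledDataset(ds.images[idx], ds.labels[idx], ds.split,
                              dict(ds.provenance, subset=n))


# --------------------------------------------------------------------- recipes

def _run_yerkes_dodson(study: Study) -> Dict[str, pd.DataFrame]:
    cfg = study.config
    grid = cfg.gain_grid()
    profiles, peak_rows = [], []
    for level in cfg.levels:
        prof = sweep(study.backbone(), study.heads(level),
                     study.suite()[level]["test"], grid, condition=level,
                     calib=study.calib(level))
        profiles.append(prof)
        for metric in ("accuracy", "dprime", "criterion"):
            pk = find_peak(prof, metric=metric)
            peak_rows.append(
                {
                    "condition": level, "metric": metric,
                    "median_peak_delta": pk.median, "mean_peak_delta": pk.mean,
                    "ci_low": pk.ci_low, "ci_high": pk.ci_high,
                    "peaks": json.dumps(list(pk.peaks)),
                }
            )
    return {
        "profile": pd.concat(profiles, ignore_index=True),
        "peaks": pd.DataFrame(peak_rows),
    }


def _run_answer_options(study: Study) -> Dict[str, pd.DataFrame]:
    cfg = study.config
    grid = cfg.gain_grid()
    splits = study.category_splits()
    backbone = study.backbone()
    subsets = subsample_answer_options(
        range(cfg.pretrain_categories), cfg.option_sizes,
        cfg.option_iterations, seed=stage_seed(cfg.seed, "options"),
    )
    head_cfg = study.config.head_config()
    profiles = []
    for size, subset_list in subsets.items():
        heads = [
            finetune_category_head(
                backbone, splits, classes, head_cfg, instance=i,
                condition=f"options-{size}",
            )
            for i, classes in enumerate(subset_list)
        ]
        profiles.append(
            sweep_category(backbone, heads, splits["test"], grid,
                           calib=splits["train"].as_nchw())
        )
    profile = pd.concat(profiles, ignore_index=True)
    peak_rows = []
    for cond, g in profile.groupby("condition"):
        pk = find_peak(g, metric="auc")
        peak_rows.append(
            {
                "condition": cond, "metric": "auc",
                "median_peak_delta": pk.median, "mean_peak_delta": pk.mean,
                "ci_low": pk.ci_low, "ci_high": pk.ci_high,
            }
        )
    return {"profile": profile, "peaks": pd.DataFrame(peak_rows)}


def _run_decoding(study: Study) -> Dict[str, pd.DataFrame]:
    cfg = study.config
    grid = cfg.probe_grid()
    backbone = study.backbone()
    rows, act_rows = [], []
    for level in cfg.levels:
        splits = study.suite()[level]
        pool_images = np.concatenate(
            [splits[s].images for s in ("train", "val", "test")]
        )
        pool_labels = np.concatenate(
            [splits[s].labels for s in ("train", "val", "test")]
        )
        pool = LabeledDataset(pool_images, pool_labels, "pool", {})
        x = pool.as_nchw()
        states = GainStateCache(backbone, grid, study.calib(level))
        for delta in grid:
            states.enter(delta)
            taps, _, _ = forward_with_taps(backbone, x)
            for block, act in mean_activation(taps).items():
                act_rows.append(
                    {"level": level, "delta": delta, "block": block,
                     "mean_activation": act}
                )
            for block, tap in taps.items():
                rec = decode_block(
                    tap, pool.labels,
                    n_train=cfg.probe_n_train, n_test=cfg.probe_n_test,
                    n_iter=cfg.probe_n_iter,
                    seed=stage_seed(cfg.seed, f"probe-{level}-{delta}-{block}"),
                    max_dim=cfg.probe_max_dim,
                )
                for _, r in rec.iterrows():
                    rows.append(
                        {"level": level, "delta": delta, "block": block,
                         "iteration": int(r["iteration"]),
                         "accuracy": float(r["accuracy"])}
                    )
        states.neutral()
    records = pd.DataFrame(rows)
    per_level, per_block, excluded = decoding_peak_gain(
        records, ceiling_threshold=cfg.ceiling_threshold
    )
    info_rows = []
    for (level, delta), g in records.groupby(["level", "delta"]):
        accs = g.groupby("block")["accuracy"].mean().to_dict()
        info = most_informative_block(accs)
        info_rows.append(
            {"level": level, "delta": delta,
             "first_best": info.first_best, "last_best": info.last_best}
        )
    return {
        "records": records,
        "activation": pd.DataFrame(act_rows),
        "peaks_per_level": per_level,
        "peaks_per_block": per_block,
        "informative_blocks": pd.DataFrame(info_rows),
    }


def _run_scrambling(study: Study, level: Optional[float] = None) -> Dict[str, pd.DataFrame]:
    cfg = study.config
    level = level if level is not None else max(cfg.levels)
    backbone = study.backbone()
    heads = study.heads(level)
    test = study.test_set(level, cfg.scramble_test_n)
    grid = cfg.scramble_grid()
    n_blocks = backbone.config.n_blocks
    states = GainStateCache(backbone, grid, study.calib(level))

    # importance curves + calibration at neutral gain, instance 0
    cal_rows, curve_rows, rates = [], [], {}
    for block in range(1, n_blocks + 1):
        states.neutral()
        curve = importance_curve(
            backbone, heads[0], block, test,
            p_grid=cfg.scramble_p_grid, n_rep=cfg.scramble_reps,
            seed=stage_seed(cfg.seed, f"importance-{block}"),
        )
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            cal = calibrate_rate(curve, cfg.retention_threshold)
        rates[block] = cal.p_star
        cal_rows.append(
            {"block": block, "p_star": cal.p_star,
             "threshold": cfg.retention_threshold, "reached": cal.reached}
        )
        for p, m, s in zip(curve.p_grid, curve.mean_accuracy, curve.sd_accuracy):
            curve_rows.append(
                {"block": block, "p": float(p), "mean_accuracy": float(m),
                 "sd_accuracy": float(s)}
            )

    # unperturbed reference sweep on the same grid/test set
    ref = sweep(backbone, heads, test, grid, condition=level, states=states)
    ref_peak = find_peak(ref, metric="accuracy")

    stage_frames = []
    for direction in ("late_to_early", "early_to_late"):
        plans = progressive_plans(
            n_blocks, direction, rates,
            seed=stage_seed(cfg.seed, f"scramble-{direction}"),
        )
        prof = progressive_scramble_sweep(
            backbone, heads, plans, test, grid, n_rep=cfg.scramble_reps,
            states=states,
        )
        stage_frames.append(prof)
    profile = pd.concat(stage_frames, ignore_index=True)
    peaks = (
        profile.groupby("direction")
        .apply(stage_peaks, include_groups=False)
        .reset_index(level=0)
        .reset_index(drop=True)
    )
    peaks["unperturbed_median_peak"] = ref_peak.median
    return {
        "importance_curves": pd.DataFrame(curve_rows),
        "calibration": pd.DataFrame(cal_rows),
        "reference_profile": ref,
        "profile": profile,
        "stage_peaks": peaks,
    }


# -------------------------------------------------------------------- manifest

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_experiment(
    recipe: str,
    config: StudyConfig,
    out_dir,
    level: Optional[float] = None,
) -> Dict[str, pd.DataFrame]:
    """Run one recipe end-to-end, writing CSV tables and a manifest."""
    if recipe not in RECIPES:
        raise ValueError(f"unknown recipe {recipe!r}; choose from {RECIPES}")
    config.gain_grid()  # validates the grid (contains 1.0) before any compute
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    study = Study(config, out_dir)
    if recipe == "yerkes_dodson":
        tables = _run_yerkes_dodson(study)
    elif recipe == "answer_options":
        tables = _run_answer_options(study)
    elif recipe == "decoding":
        tables = _run_decoding(study)
    else:
        tables = _run_scrambling(study, level=level)

    outputs = {}
    for name, df in tables.items():
        if df.isna().all(axis=None) or not np.all(
            np.isfinite(df.select_dtypes(include=[np.number]).fillna(0.0).to_numpy())
        ):
            raise RuntimeError(f"non-finite values in output table {name!r}")
        path = out_dir / f"{recipe}_{name}.csv"
        df.to_csv(path, index=False)
        outputs[name] = {"path": str(path), "sha256": _sha256(path)}

    from importlib.metadata import version as _pkg_version

    try:
        pkg_version = _pkg_version("gainsweep")
    except Exception:
        pkg_version = "unknown"
    manifest = {
        "recipe": recipe,
        "config": asdict(config),
        "seed": config.seed,
        "package_version": pkg_version,
        "outputs": outputs,
    }
    (out_dir / f"{recipe}_manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str)
    )
    return tables
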