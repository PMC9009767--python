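"""Procedural image stimuli for the arousal-gain experiments.

Two task families are generated, both fully synthetic so the entire
pipeline runs without any external dataset:

* **Real-vs-average discrimination.** "Real" images are procedurally
  structured scenes — multi-scale oriented gratings under smooth
  envelopes plus polygonal occluders, min-max normalised to [0, 1].
  "Average" images are (weighted) pixel means of ``k`` real-style source
  images drawn from a pool disjoint from the real-class pool. Averaging
  attenuates contrast and high-frequency structure in proportion to
  ``k``, so ``k`` acts as a parametric difficulty dial: ``k = 1.25``
  (one image plus a second at 25 % weight) is barely distinguishable
  from a single image, ``k = 40`` is a washed-out blur. Averages are
  deliberately *not* re-normalised — the contrast loss is the cue the
  task is built on (a ``renormalize`` flag exposes the alternative).

* **Category recognition.** Images whose category is defined by a
  conjunction of grating orientation, occluder shape and a mild
  multiplicative colour tint on a shared uninformative background. The
  tint makes categories linearly identifiable from raw pixels by
  construction, which anchors probe calibration tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from skimage.draw import polygon as _sk_polygon

F32 = np.float32

__all__ = [
    "StyleParams",
    "DifficultyLevel",
    "LabeledDataset",
    "generate_real_images",
    "make_average_image",
    "build_difficulty_suite",
    "generate_category_dataset",
    "split_dataset",
    "save_dataset",
    "load_dataset",
]


@dataclass(frozen=True)
class StyleParams:
    """Knobs of the procedural scene generator."""

    image_size: int = 64
    channels: int = 3
    n_gratings: int = 4
    n_blobs: int = 3
    freq_range: Tuple[float, float] = (0.04, 0.35)  # cycles / pixel
    blob_frac: Tuple[float, float] = (0.12, 0.4)    # blob radius / image size
    grating_amp: Tuple[float, float] = (0.4, 1.0)
    # per-image pixel SD and mean luminance are drawn from these ranges,
    # mimicking the heterogeneity of natural photographs; blends of k
    # sources attenuate contrast ~1/sqrt(k), so the ranges keep large-k
    # averages clearly flatter than any single scene while small-k blends
    # overlap the real-image distribution
    contrast_range: Tuple[float, float] = (0.12, 0.30)
    luminance_range: Tuple[float, float] = (0.4, 0.6)

    def __post_init__(self):
        if self.image_size < 8 or self.channels not in (1, 3):
            raise ValueError("invalid image geometry")
        if not (0 < self.freq_range[0] < self.freq_range[1] <= 0.5):
            raise ValueError("freq_range must satisfy 0 < lo < hi <= 0.5")
        if self.n_gratings < 1:
            raise ValueError("need at least one grating component")


@dataclass(frozen=True)
class DifficultyLevel:
    """Number of images blended per average image.

    Fractional ``k = n + alpha`` (0 < alpha < 1) blends ``n`` images at
    full weight plus one at weight ``alpha``, normalised by ``k`` — e.g.
    ``k = 1.25`` is one image plus a second at 25 % alpha. ``k = 1``
    reproduces a single source image exactly. Larger ``k`` makes the
    average easier to tell from a real image.
    """

    k: float

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("difficulty level k must be >= 1")

    @property
    def n_sources(self) -> int:
        return int(math.ceil(self.k))

    def weights(self) -> np.ndarray:
        n_full = int(math.floor(self.k))
        frac = self.k - n_full
        if frac < 1e-12:
            w = np.ones(n_full)
        else:
            w = np.concatenate([np.ones(n_full), [frac]])
        return (w / self.k).astype(np.float64)


@dataclass
class LabeledDataset:
    """Images (N, H, W, C float32 in [0,1]) with integer labels."""

    images: np.ndarray
    labels: np.ndarray
    split: str
    provenance: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=F32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels length mismatch")
        if self.images.ndim != 4:
            raise ValueError("images must be (N, H, W, C)")
        lo, hi = float(self.images.min(initial=0.0)), float(self.images.max(initial=1.0))
        if lo < -1e-6 or hi > 1 + 1e-6:
            raise ValueError(f"pixel values outside [0, 1]: [{lo}, {hi}]")

    def __len__(self) -> int:
        return len(self.images)

    def as_nchw(self) -> np.ndarray:
        return np.ascontiguousarray(self.images.transpose(0, 3, 1, 2))


# --------------------------------------------------------------------- scenes

def _render_scene(rng: np.random.Generator, style: StyleParams) -> np.ndarray:
    """One structured scene: oriented gratings + polygonal occluders,
    min-max normalised to [0, 1]."""
    s = style.image_size
    yy, xx = np.mgrid[0:s, 0:s].astype(F32)
    gray = np.zeros((s, s), dtype=F32)
    lo, hi = style.freq_range
    for _ in range(style.n_gratings):
        theta = rng.uniform(0, np.pi)
        freq = np.exp(rng.uniform(np.log(lo), np.log(hi)))
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(*style.grating_amp)
        u = np.cos(theta) * xx + np.sin(theta) * yy
        cy, cx = rng.uniform(0, s, size=2)
        sigma = rng.uniform(0.25, 0.7) * s
        env = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)))
        gray += amp * env * np.sin(2 * np.pi * freq * u + phase)

    mix = rng.uniform(0.55, 1.0, size=style.channels).astype(F32)
    img = gray[:, :, None] * mix[None, None, :]

    for _ in range(style.n_blobs):
        n_vert = rng.integers(3, 7)
        cy, cx = rng.uniform(0.15 * s, 0.85 * s, size=2)
        radius = rng.uniform(*style.blob_frac) * s
        ang = np.sort(rng.uniform(0, 2 * np.pi, size=n_vert))
        ry = cy + radius * np.sin(ang) * rng.uniform(0.6, 1.0, size=n_vert)
        rx = cx + radius * np.cos(ang) * rng.uniform(0.6, 1.0, size=n_vert)
        rr, cc = _sk_polygon(ry, rx, shape=(s, s))
        color = rng.uniform(-1.2, 1.2, size=style.channels).astype(F32)
        alpha = rng.uniform(0.5, 0.9)
        img[rr, cc, :] = (1 - alpha) * img[rr, cc, :] + alpha * color[None, :]

    lo_v, hi_v = img.min(), img.max()
    img = (img - lo_v) / (hi_v - lo_v + 1e-8)
    contrast = rng.uniform(*style.contrast_range)
    lum = rng.uniform(*style.luminance_range)
    img = lum + (img - img.mean()) * (contrast / (img.std() + 1e-8))
    return np.clip(img, 0.0, 1.0).astype(F32)


def generate_real_images(
    n: int, seed: int, style_params: Optional[StyleParams] = None
) -> LabeledDataset:
    """Generate ``n`` procedural real-class images, deterministic in ``seed``."""
    if n <= 0:
        raise ValueError("n must be > 0")
    style = style_params or StyleParams()
    rng = np.random.default_rng(seed)
    images = np.stack([_render_scene(rng, style) for _ in range(n)])
    return LabeledDataset(
        images=images,
        labels=np.ones(n, dtype=np.int64),
        split="pool",
        provenance={"generator": "real", "n": n, "seed": seed, "style": repr(style)},
    )


def make_average_image(
    sources: Sequence[np.ndarray], k: DifficultyLevel | float
) -> np.ndarray:
    """Weighted pixel mean of ``ceil(k)`` source images (see
    :class:`DifficultyLevel` for the fractional-``k`` weight rule)."""
    if not isinstance(k, DifficultyLevel):
        k = DifficultyLevel(float(k))
    sources = [np.asarray(s, dtype=F32) for s in sources]
    if len(sources) != k.n_sources:
        raise ValueError(
            f"k={k.k} requires ceil(k)={k.n_sources} sources, got {len(sources)}"
        )
    w = k.weights()
    out = np.tensordot(w.astype(F32), np.stack(sources), axes=(0, 0))
    return np.clip(out, 0.0, 1.0).astype(F32)


# ------------------------------------------------------------ difficulty suite

def build_difficulty_suite(
    levels: Sequence[DifficultyLevel | float],
    n_per_split: Tuple[int, int, int] = (2000, 600, 600),
    seed: int = 0,
    style_params: Optional[StyleParams] = None,
    renormalize: bool = False,
) -> Dict[float, Dict[str, LabeledDataset]]:
    """Balanced train/val/test triplets for each difficulty level.

    Real-class images are shared across levels; average images are
    rebuilt per level from a source pool disjoint from the real-class
    pool. Splits use disjoint image pools throughout. Labels: real = 1,
    average = 0, exactly balanced.
    """
    levels = [l if isinstance(l, DifficultyLevel) else DifficultyLevel(float(l))
              for l in levels]
    if not levels:
        raise ValueError("levels must be non-empty")
    style = style_params or StyleParams()
    split_names = ("train", "val", "test")
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(len(split_names))

    suite: Dict[float, Dict[str, LabeledDataset]] = {l.k: {} for l in levels}
    kmax = max(l.n_sources for l in levels)

    for split, n_split, split_ss in zip(split_names, n_per_split, child):
        if n_split % 2:
            raise ValueError("split sizes must be even for exact 50/50 balance")
        n_half = n_split // 2
        seeds = split_ss.generate_state(4)
        real = generate_real_images(n_half, int(seeds[0] % (2**31)), style).images
        pool_size = n_half + max(kmax + 1, 64)
        pool = generate_real_images(n_half + max(kmax + 1, 64),
                                    int(seeds[1] % (2**31)), style).images
        for level in levels:
            rng = np.random.default_rng([int(seeds[2] % (2**31)),
                                         int(level.k * 1000)])
            averages = np.empty_like(real)
            for i in range(n_half):
                extra = rng.choice(pool_size - 1, size=level.n_sources - 1,
                                   replace=False)
                # offset so source i is always the full-weight base image
                idx = np.concatenate([[i], (i + 1 + extra) % pool_size])
                averages[i] = make_average_image(list(pool[idx]), level)
            if renormalize:
                lo = averages.min(axis=(1, 2, 3), keepdims=True)
                hi = averages.max(axis=(1, 2, 3), keepdims=True)
                averages = (averages - lo) / (hi - lo + 1e-8)
            images = np.concatenate([real, averages])
            labels = np.concatenate(
                [np.ones(n_half, dtype=np.int64), np.zeros(n_half, dtype=np.int64)]
            )
            order = np.random.default_rng(
                [int(seeds[3] % (2**31)), int(level.k * 1000)]
            ).permutation(n_split)
            suite[level.k][split] = LabeledDataset(
                images=images[order],
                labels=labels[order],
                split=split,
                provenance={
                    "task": "real_vs_average",
                    "level": level.k,
                    "seed": seed,
                    "n": n_split,
                    "renormalize": renormalize,
                    "style": repr(style),
                },
            )
    return suite


# ----------------------------------------------------------- category stimuli

_SHAPES = ("disc", "square", "triangle", "plus")

# distinct unit-ish RGB tints; mild multiplicative application keeps the
# categories linearly identifiable without trivialising the CNN task
_TINTS = np.array(
    [
        [1.0, 0.3, 0.3], [0.3, 1.0, 0.3], [0.3, 0.3, 1.0], [1.0, 1.0, 0.3],
        [1.0, 0.3, 1.0], [0.3, 1.0, 1.0], [1.0, 0.65, 0.3], [0.6, 0.6, 0.6],
    ],
    dtype=F32,
)


def _draw_shape(img: np.ndarray, shape: str, rng: np.random.Generator,
                color: np.ndarray) -> None:
    s = img.shape[0]
    cy, cx = rng.uniform(0.3 * s, 0.7 * s, size=2)
    r = rng.uniform(0.12, 0.22) * s
    yy, xx = np.mgrid[0:s, 0:s]
    if shape == "disc":
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    elif shape == "square":
        mask = (np.abs(yy - cy) <= r) & (np.abs(xx - cx) <= r)
    elif shape == "triangle":
        mask = (yy - cy <= r) & (np.abs(xx - cx) * 1.8 <= (yy - cy + r))
    else:  # plus
        mask = ((np.abs(yy - cy) <= 0.35 * r) & (np.abs(xx - cx) <= r)) | (
            (np.abs(xx - cx) <= 0.35 * r) & (np.abs(yy - cy) <= r)
        )
    img[mask] = 0.35 * img[mask] + 0.65 * color[None, :]


def generate_category_dataset(
    n_categories: int,
    n_per_category: int,
    seed: int,
    style_params: Optional[StyleParams] = None,
) -> LabeledDataset:
    """Balanced multi-category stimuli over procedural scene backgrounds.

    Category ``i`` is defined by grating orientation ``i*pi/n``, an
    occluder shape family, and tint ``i`` of a fixed palette, composited
    onto the same scene-texture distribution the discrimination task
    uses — so a backbone pretrained on these categories learns features
    matched to the task domain.
    """
    if n_categories < 2:
        raise ValueError("need at least 2 categories")
    if n_categories > len(_TINTS):
        raise ValueError(f"at most {len(_TINTS)} categories supported")
    style = style_params or StyleParams()
    s = style.image_size
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:s, 0:s].astype(F32)

    images, labels = [], []
    for i in range(n_categories):
        theta = i * np.pi / n_categories
        tint = _TINTS[i]
        shape = _SHAPES[i % len(_SHAPES)]
        for _ in range(n_per_category):
            img = _render_scene(rng, style).copy()
            freq = np.exp(rng.uniform(np.log(0.08), np.log(0.2)))
            phase = rng.uniform(0, 2 * np.pi)
            u = np.cos(theta) * xx + np.sin(theta) * yy
            grating = 0.25 * np.sin(2 * np.pi * freq * u + phase)
            img = img + grating[:, :, None]
            _draw_shape(img, shape, rng, tint)
            img = img * (0.82 + 0.18 * tint)[None, None, :]
            images.append(np.clip(img, 0, 1).astype(F32))
            labels.append(i)
    images = np.stack(images)
    labels = np.asarray(labels, dtype=np.int64)
    order = rng.permutation(len(labels))
    return LabeledDataset(
        images=images[order],
        labels=labels[order],
        split="all",
        provenance={
            "task": "category",
            "n_categories": n_categories,
            "n_per_category": n_per_category,
            "seed": seed,
            "style": repr(style),
        },
    )


def split_dataset(
    ds: LabeledDataset, fractions: Tuple[float, float, float] = (0.7, 0.15, 0.15),
    seed: int = 0,
) -> Dict[str, LabeledDataset]:
    """Stratified disjoint train/val/test partition of one dataset."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    idx_by_split: Dict[str, List[int]] = {"train": [], "val": [], "test": []}
    for cls in np.unique(ds.labels):
        idx = np.flatnonzero(ds.labels == cls)
        idx = rng.permutation(idx)
        n_tr = int(round(fractions[0] * len(idx)))
        n_va = int(round(fractions[1] * len(idx)))
        idx_by_split["train"].extend(idx[:n_tr])
        idx_by_split["val"].extend(idx[n_tr : n_tr + n_va])
        idx_by_split["test"].extend(idx[n_tr + n_va :])
    out = {}
    for split, idx in idx_by_split.items():
        idx = rng.permutation(np.asarray(idx, dtype=np.int64))
        out[split] = LabeledDataset(
            images=ds.images[idx],
            labels=ds.labels[idx],
            split=split,
            provenance=dict(ds.provenance, parent_split=ds.split),
        )
    return out


# ---------------------------------------------------------------------- disk IO

def save_dataset(ds: LabeledDataset, out_dir, prefix: str = "img",
                 level: Optional[float] = None, seed: Optional[int] = None) -> Path:
    """Write PNG images plus a CSV manifest; returns the manifest path."""
    import pandas as pd
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, label) in enumerate(zip(ds.images, ds.labels)):
        name = f"{prefix}_{ds.split}_{i:05d}.png"
        arr = np.clip(img * 255.0 + 0.5, 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(out_dir / name)
        rows.append(
            {"path": name, "label": int(label), "split": ds.split,
             "level": level if level is not None else "", "seed": seed if seed is not None else ""}
        )
    manifest = out_dir / f"{prefix}_{ds.split}_manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_dataset(manifest_path) -> LabeledDataset:
    """Read a dataset back from a PNG + CSV manifest directory."""
    import pandas as pd
    from PIL import Image

    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    base = manifest_path.parent
    images = np.stack(
        [np.asarray(Image.open(base / p), dtype=F32) / 255.0 for p in df["path"]]
    )
    if images.ndim == 3:
        images = images[..., None]
    return LabeledDataset(
        images=images,
        labels=df["label"].to_numpy(),
        split=str(df["split"].iloc[0]),
        provenance={"manifest": str(manifest_path)},
    )
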