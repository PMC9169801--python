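"""Synthetic leaf scenes with exact ground-truth masks.

The simulator stands in for photographic leaf datasets so that every sample
carries a pixel-exact reference: a foreground mask from the renderer, a
lesion (transparent-circle) region, and the binary *annotation matrix* used
both to guide training (1 = useless pixel) and, via its complement, to assess
explanations.

Three classification tasks are generated:

``fake_vs_real``
    untouched scenes (class 0) versus scenes with randomly placed transparent
    circles (class 1); annotations mark everything outside the circles.
``diseased_vs_healthy``
    clean leaves versus leaves with opaque brown blotches; annotations mark
    the scene background.
``species``
    procedurally distinct leaf silhouettes (round / elongated / trilobed);
    annotations mark pixels outside the leaf's minimum bounding rectangle.

All generation is deterministic given ``(config, seed)``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "SceneConfig",
    "Sample",
    "LabeledDataset",
    "generate_leaf_scene",
    "add_transparent_circles",
    "add_lesion_blotches",
    "annotation_from_circles",
    "annotation_from_background",
    "annotation_from_bounding_rect",
    "build_dataset",
    "build_watermark_dataset",
    "save_dataset",
    "load_dataset",
]

TASKS = ("fake_vs_real", "diseased_vs_healthy", "species")
SPECIES_SHAPES = ("round", "elongated", "trilobed")

# deterministic substream tags
_T_SCENE, _T_CIRCLES, _T_LESIONS, _T_SPLIT = 11, 13, 17, 19


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of the procedural leaf renderer and the circle injector.

    Radii are fractions of ``min(U, V)``; opacity 1.0 replaces the pixel with
    the background colour entirely.
    """

    image_size: tuple[int, int] = (64, 64)
    n_circles_range: tuple[int, int] = (1, 5)
    radius_range: tuple[float, float] = (0.05, 0.15)
    alpha_range: tuple[float, float] = (0.3, 0.7)
    allow_background_circles: bool = True
    background_style: str = "flat"  # or "textured"
    background_color: tuple[float, float, float] = (0.80, 0.76, 0.66)

    def validate(self) -> None:
        U, V = self.image_size
        if U < 32 or V < 32:
            raise ValueError(f"image_size must be at least 32x32, got {self.image_size}")
        lo, hi = self.n_circles_range
        if not (0 <= lo <= hi):
            raise ValueError(f"invalid n_circles_range {self.n_circles_range}")
        rlo, rhi = self.radius_range
        if not (0 < rlo <= rhi < 0.5):
            raise ValueError(f"invalid radius_range {self.radius_range}")
        alo, ahi = self.alpha_range
        if not (0 < alo <= ahi <= 1.0):
            raise ValueError(f"invalid alpha_range {self.alpha_range}")
        if self.background_style not in ("flat", "textured"):
            raise ValueError(f"unknown background_style {self.background_style!r}")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "SceneConfig":
        d = json.loads(text)
        for k in ("image_size", "n_circles_range", "radius_range", "alpha_range",
                  "background_color"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class Sample:
    image: np.ndarray          # (U, V, 3) float32 in [0, 1]
    label: int
    annotation: np.ndarray     # (U, V) uint8, 1 = useless pixel
    assessment: np.ndarray     # (U, V) uint8, 1 = useful-region pixel


@dataclass
class LabeledDataset:
    samples: list[Sample]
    splits: dict[str, np.ndarray]
    class_names: list[str]
    task: str = ""

    def __len__(self) -> int:
        return len(self.samples)

    def split_arrays(self, split: str):
        """Stacked (images NCHW float32, labels, annotations, assessments)."""
        idx = self.splits[split]
        if len(idx) == 0:
            raise ValueError(f"split {split!r} is empty")
        imgs = np.stack([self.samples[i].image for i in idx]).transpose(0, 3, 1, 2)
        labels = np.array([self.samples[i].label for i in idx], dtype=np.int64)
        anns = np.stack([self.samples[i].annotation for i in idx]).astype(np.float32)
        assm = np.stack([self.samples[i].assessment for i in idx])
        return np.ascontiguousarray(imgs, dtype=np.float32), labels, anns, assm


# --------------------------------------------------------------------------
# scene rendering
# --------------------------------------------------------------------------

def _rng(seed: int, tag: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, tag, index])


def _smooth_noise(rng: np.random.Generator, U: int, V: int, cells: int = 6) -> np.ndarray:
    """Low-frequency noise in [-1, 1]: coarse grid, bilinear upsample."""
    coarse = rng.uniform(-1.0, 1.0, size=(cells, cells))
    rr = np.linspace(0, cells - 1, U)
    cc = np.linspace(0, cells - 1, V)
    r0 = np.floor(rr).astype(int).clip(0, cells - 2)
    c0 = np.floor(cc).astype(int).clip(0, cells - 2)
    fr = (rr - r0)[:, None]
    fc = (cc - c0)[None, :]
    a = coarse[np.ix_(r0, c0)]
    b = coarse[np.ix_(r0, c0 + 1)]
    c = coarse[np.ix_(r0 + 1, c0)]
    d = coarse[np.ix_(r0 + 1, c0 + 1)]
    return (a * (1 - fr) * (1 - fc) + b * (1 - fr) * fc
            + c * fr * (1 - fc) + d * fr * fc)


def _ellipse_mask(U: int, V: int, cy: float, cx: float, ry: float, rx: float,
                  theta: float) -> np.ndarray:
    rr, cc = np.mgrid[0:U, 0:V].astype(np.float64)
    dy, dx = rr - cy, cc - cx
    ct, st = math.cos(theta), math.sin(theta)
    u = dy * ct + dx * st
    v = -dy * st + dx * ct
    return (u / ry) ** 2 + (v / rx) ** 2 <= 1.0


def _leaf_silhouette(rng: np.random.Generator, U: int, V: int,
                     shape: str) -> np.ndarray:
    m = min(U, V)
    cy = U / 2 + rng.uniform(-0.05, 0.05) * U
    cx = V / 2 + rng.uniform(-0.05, 0.05) * V
    theta = rng.uniform(0, math.pi)
    if shape == "round":
        ry = rng.uniform(0.30, 0.40) * m
        rx = rng.uniform(0.24, 0.34) * m
        return _ellipse_mask(U, V, cy, cx, ry, rx, theta)
    if shape == "elongated":
        ry = rng.uniform(0.38, 0.46) * m
        rx = rng.uniform(0.10, 0.16) * m
        return _ellipse_mask(U, V, cy, cx, ry, rx, theta)
    if shape == "trilobed":
        mask = np.zeros((U, V), dtype=bool)
        for dth in (-0.9, 0.0, 0.9):
            ry = rng.uniform(0.26, 0.34) * m
            rx = rng.uniform(0.10, 0.15) * m
            mask |= _ellipse_mask(U, V, cy, cx, ry, rx, theta + dth)
        return mask
    raise ValueError(f"unknown leaf shape {shape!r}")


def generate_leaf_scene(cfg: SceneConfig, seed: int, shape: str = "round"):
    """Render one leaf scene.

    Returns ``(image, foreground)`` where the image is (U, V, 3) float32 in
    [0, 1] and the foreground mask marks leaf pixels exactly.  Deterministic
    in ``(cfg, seed, shape)``.
    """
    cfg.validate()
    U, V = cfg.image_size
    rng = _rng(seed, _T_SCENE)

    fg = _leaf_silhouette(rng, U, V, shape)
    if not fg.any():
        raise ValueError("degenerate scene: leaf silhouette covers zero pixels")

    img = np.empty((U, V, 3), dtype=np.float64)
    img[:] = cfg.background_color
    if cfg.background_style == "textured":
        tex = _smooth_noise(rng, U, V, cells=5)
        img += 0.04 * tex[:, :, None]
    else:
        # consume the same stream so flat/textured scenes stay comparable
        _smooth_noise(rng, U, V, cells=5)

    base = np.array([0.20, 0.45, 0.16]) + rng.uniform(-0.04, 0.04, size=3)
    leaf_tex = _smooth_noise(rng, U, V, cells=7)
    leaf = base[None, None, :] + 0.06 * leaf_tex[:, :, None]
    img[fg] = leaf[fg]
    return np.clip(img, 0.0, 1.0).astype(np.float32), fg.astype(np.uint8)


def _disk_mask(U: int, V: int, cy: float, cx: float, rad: float) -> np.ndarray:
    rr, cc = np.mgrid[0:U, 0:V].astype(np.float64)
    return (rr - cy) ** 2 + (cc - cx) ** 2 <= rad ** 2


def add_transparent_circles(img: np.ndarray, cfg: SceneConfig, seed: int,
                            foreground: np.ndarray | None = None):
    """Alpha-blend random transparent circles toward the background colour.

    A pixel inside a circle becomes ``(1 - alpha) * pixel + alpha * bg``; the
    returned ``circle_region`` marks the exact union of the rasterized disks
    (pixel (r, c) is inside a disk iff (r-cy)^2 + (c-cx)^2 <= rad^2).  When
    ``allow_background_circles`` is false a foreground mask must be supplied
    and circle centres are drawn from it.
    """
    cfg.validate()
    U, V = img.shape[:2]
    rng = _rng(seed, _T_CIRCLES)
    out = img.astype(np.float64).copy()
    region = np.zeros((U, V), dtype=bool)
    n = int(rng.integers(cfg.n_circles_range[0], cfg.n_circles_range[1] + 1))
    bg = np.array(cfg.background_color)
    for _ in range(n):
        if cfg.allow_background_circles:
            cy = rng.uniform(0, U - 1)
            cx = rng.uniform(0, V - 1)
        else:
            if foreground is None:
                raise ValueError("foreground mask required when background "
                                 "circles are disallowed")
            ys, xs = np.nonzero(foreground)
            j = int(rng.integers(0, len(ys)))
            cy, cx = float(ys[j]), float(xs[j])
        rad = rng.uniform(*cfg.radius_range) * min(U, V)
        alpha = rng.uniform(*cfg.alpha_range)
        disk = _disk_mask(U, V, cy, cx, rad)
        out[disk] = (1.0 - alpha) * out[disk] + alpha * bg
        region |= disk
    return np.clip(out, 0.0, 1.0).astype(np.float32), region.astype(np.uint8)


def add_lesion_blotches(img: np.ndarray, foreground: np.ndarray, seed: int,
                        n_range: tuple[int, int] = (3, 8),
                        radius_range: tuple[float, float] = (0.03, 0.07)):
    """Stamp opaque brown blotches inside the leaf (disease texture)."""
    U, V = img.shape[:2]
    rng = _rng(seed, _T_LESIONS)
    out = img.astype(np.float64).copy()
    region = np.zeros((U, V), dtype=bool)
    ys, xs = np.nonzero(foreground)
    if len(ys) == 0:
        raise ValueError("empty foreground")
    n = int(rng.integers(n_range[0], n_range[1] + 1))
    for _ in range(n):
        j = int(rng.integers(0, len(ys)))
        rad = rng.uniform(*radius_range) * min(U, V)
        disk = _disk_mask(U, V, float(ys[j]), float(xs[j]), rad) & (foreground > 0)
        color = np.array([0.38, 0.24, 0.08]) + rng.uniform(-0.04, 0.04, size=3)
        out[disk] = 0.15 * out[disk] + 0.85 * color
        region |= disk
    return np.clip(out, 0.0, 1.0).astype(np.float32), region.astype(np.uint8)


# --------------------------------------------------------------------------
# annotation matrices (1 = useless pixel)
# --------------------------------------------------------------------------

def annotation_from_circles(circle_region: np.ndarray) -> np.ndarray:
    """Useless pixels are everything outside the injected circles."""
    return (circle_region == 0).astype(np.uint8)


def annotation_from_background(foreground: np.ndarray) -> np.ndarray:
    """Useless pixels are the scene background (exact for synthetic scenes)."""
    return (foreground == 0).astype(np.uint8)


def annotation_from_bounding_rect(foreground: np.ndarray) -> np.ndarray:
    """Useless pixels lie strictly outside the leaf's minimum bounding
    rectangle (axis-aligned, bounds inclusive)."""
    ys, xs = np.nonzero(foreground)
    if len(ys) == 0:
        raise ValueError("empty foreground: bounding rectangle undefined")
    ann = np.ones(foreground.shape, dtype=np.uint8)
    ann[ys.min():ys.max() + 1, xs.min():xs.max() + 1] = 0
    return ann


# --------------------------------------------------------------------------
# dataset assembly
# --------------------------------------------------------------------------

def _stratified_splits(labels: np.ndarray, fracs: tuple[float, float, float],
                       seed: int) -> dict[str, np.ndarray]:
    if abs(sum(fracs) - 1.0) > 1e-8:
        raise ValueError(f"split fractions must sum to 1, got {fracs}")
    rng = _rng(seed, _T_SPLIT)
    names = ("train", "validation", "test")
    parts: dict[str, list[int]] = {n: [] for n in names}
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        rng.shuffle(idx)
        n = len(idx)
        # largest-remainder allocation so per-class counts differ by <= 1
        raw = np.array(fracs) * n
        counts = np.floor(raw).astype(int)
        order = np.argsort(-(raw - counts), kind="stable")
        for j in order[: n - counts.sum()]:
            counts[j] += 1
        pos = 0
        for name, c in zip(names, counts):
            parts[name].extend(idx[pos:pos + c].tolist())
            pos += c
    return {n: np.array(sorted(v), dtype=np.int64) for n, v in parts.items()}


def build_dataset(task: str, cfg: SceneConfig, n_samples: int,
                  split_fracs: tuple[float, float, float] = (0.6, 0.2, 0.2),
                  seed: int = 0, n_species: int = 3) -> LabeledDataset:
    """Generate a complete labeled dataset for one of the three tasks.

    Samples are seed-deterministic; splits are stratified by class.  Each
    sample carries an annotation matrix (1 = useless pixel) and its
    complement as the assessment mask (1 = useful-region pixel).
    """
    cfg.validate()
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    if n_samples < 10:
        raise ValueError("n_samples must be at least 10")
    if abs(sum(split_fracs) - 1.0) > 1e-8:
        raise ValueError(f"split fractions must sum to 1, got {split_fracs}")

    samples: list[Sample] = []
    if task == "fake_vs_real":
        n_real = n_samples // 2
        for i in range(n_samples):
            img, fg = generate_leaf_scene(cfg, seed=_sample_seed(seed, i))
            if i < n_real:
                # circle-free originals carry no lesion reference; they opt out
                # of gradient guidance via the zero annotation matrix
                label = 0
                ann = np.zeros(cfg.image_size, dtype=np.uint8)
            else:
                label = 1
                img, circles = add_transparent_circles(
                    img, cfg, seed=_sample_seed(seed, i), foreground=fg)
                ann = annotation_from_circles(circles)
            samples.append(Sample(img, label, ann, (1 - ann).astype(np.uint8)))
        class_names = ["real", "fake"]
    elif task == "diseased_vs_healthy":
        n_healthy = n_samples // 2
        for i in range(n_samples):
            img, fg = generate_leaf_scene(cfg, seed=_sample_seed(seed, i))
            label = 0 if i < n_healthy else 1
            if label == 1:
                img, _ = add_lesion_blotches(img, fg, seed=_sample_seed(seed, i))
            ann = annotation_from_background(fg)
            samples.append(Sample(img, label, ann, (1 - ann).astype(np.uint8)))
        class_names = ["healthy", "diseased"]
    else:  # species
        if not (2 <= n_species <= len(SPECIES_SHAPES)):
            raise ValueError(f"n_species must be in [2, {len(SPECIES_SHAPES)}]")
        per = n_samples // n_species
        counts = [per + (1 if i < n_samples % n_species else 0)
                  for i in range(n_species)]
        i = 0
        for cls, cnt in enumerate(counts):
            for _ in range(cnt):
                img, fg = generate_leaf_scene(
                    cfg, seed=_sample_seed(seed, i), shape=SPECIES_SHAPES[cls])
                ann = annotation_from_bounding_rect(fg)
                samples.append(Sample(img, cls, ann, (1 - ann).astype(np.uint8)))
                i += 1
        class_names = list(SPECIES_SHAPES[:n_species])

    labels = np.array([s.label for s in samples])
    splits = _stratified_splits(labels, tuple(split_fracs), seed)
    return LabeledDataset(samples, splits, class_names, task=task)


def _sample_seed(seed: int, index: int) -> int:
    # stable per-sample seed; stays below 2**31
    return (int(seed) * 1_000_003 + index * 7919 + 1) & 0x7FFFFFFF


def build_watermark_dataset(cfg: SceneConfig | None = None, n_samples: int = 300,
                            split_fracs: tuple[float, float, float] = (0.7, 0.0, 0.3),
                            seed: int = 0, patch: int = 6) -> LabeledDataset:
    """A spurious-correlation (Clever Hans) benchmark.

    The true signal is the fake-vs-real circle augmentation; additionally a
    bright ``patch x patch`` square is stamped into the top-left corner of
    every class-1 image in the train and validation splits only.  A shortcut
    learner keys on the watermark and fails on the clean test split.  Every
    train/validation sample's annotation marks the corner patch as useless;
    assessment masks are the circle regions as in ``fake_vs_real``.

    The default scene uses fainter circles (opacity 0.2-0.45) than the plain
    fake-vs-real task so that the watermark is decisively the easier cue and
    an unguided learner adopts it.
    """
    if cfg is None:
        cfg = SceneConfig(image_size=(64, 64), alpha_range=(0.2, 0.45))
    ds = build_dataset("fake_vs_real", cfg, n_samples, split_fracs, seed)
    train_like = set(ds.splits["train"].tolist()) | set(ds.splits["validation"].tolist())
    for i, s in enumerate(ds.samples):
        ann = np.zeros_like(s.annotation)
        if i in train_like:
            if s.label == 1:
                s.image = s.image.copy()
                s.image[:patch, :patch, :] = 1.0
            ann[:patch, :patch] = 1
        s.annotation = ann
        # assessment stays tied to the circle region ground truth
    ds.task = "watermark_fake_vs_real"
    return ds


# --------------------------------------------------------------------------
# PNG + manifest persistence (the real-image adapter path)
# --------------------------------------------------------------------------

def _write_png(path: Path, arr: np.ndarray) -> None:
    if arr.ndim == 2:  # mask -> {0, 255}
        Image.fromarray((arr > 0).astype(np.uint8) * 255, mode="L").save(path)
    else:
        Image.fromarray(np.round(arr * 255).astype(np.uint8), mode="RGB").save(path)


def save_dataset(ds: LabeledDataset, out_dir: str | Path) -> Path:
    """Write images/masks as PNG plus a CSV manifest; returns manifest path."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    inv_split = {}
    for name, idx in ds.splits.items():
        for i in idx:
            inv_split[int(i)] = name
    for i, s in enumerate(ds.samples):
        img_p = out / "images" / f"sample_{i:05d}.png"
        ann_p = out / "images" / f"sample_{i:05d}_annotation.png"
        ass_p = out / "images" / f"sample_{i:05d}_assessment.png"
        _write_png(img_p, s.image)
        _write_png(ann_p, s.annotation)
        _write_png(ass_p, s.assessment)
        rows.append({"path": str(img_p.relative_to(out)),
                     "label": s.label,
                     "annotation_path": str(ann_p.relative_to(out)),
                     "assessment_path": str(ass_p.relative_to(out)),
                     "split": inv_split.get(i, "train")})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    meta = {"class_names": ds.class_names, "task": ds.task}
    (out / "dataset.json").write_text(json.dumps(meta))
    return manifest


def load_dataset(manifest_path: str | Path) -> LabeledDataset:
    """Read a manifest CSV (``path,label,annotation_path,assessment_path,split``)
    referencing 8-bit PNG images and {0,255} single-channel PNG masks."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    df = pd.read_csv(manifest_path)
    samples: list[Sample] = []
    split_lists: dict[str, list[int]] = {"train": [], "validation": [], "test": []}
    for i, row in df.iterrows():
        img = np.asarray(Image.open(root / row["path"]).convert("RGB"),
                         dtype=np.float32) / 255.0
        ann = (np.asarray(Image.open(root / row["annotation_path"]).convert("L"))
               > 127).astype(np.uint8)
        ass = (np.asarray(Image.open(root / row["assessment_path"]).convert("L"))
               > 127).astype(np.uint8)
        if ann.shape != img.shape[:2] or ass.shape != img.shape[:2]:
            raise ValueError(f"mask shape mismatch for sample {i}")
        samples.append(Sample(img, int(row["label"]), ann, ass))
        split_lists.setdefault(str(row["split"]), []).append(int(i))
    meta_path = root / "dataset.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        class_names, task = meta.get("class_names", []), meta.get("task", "")
    else:
        class_names = [str(c) for c in sorted({s.label for s in samples})]
        task = ""
    splits = {k: np.array(v, dtype=np.int64) for k, v in split_lists.items()}
    return LabeledDataset(samples, splits, class_names, task=task)
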