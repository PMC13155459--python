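"""Synthetic histology-like datasets and tiny teacher/student model specs.

The generator produces 8-class "stained tissue" textures: a pink, eosin-like
background scattered with darker Gaussian blobs whose density, radius and hue
vary per class. Adjacent classes share closely overlapping texture parameters,
emulating the fine-grained benign/malignant subtype structure of breast-cancer
patch datasets (high intra-class variability, low inter-class separability)
without any external download.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InvalidSpecError

__all__ = [
    "SyntheticDatasetSpec",
    "ModelSpec",
    "DEFAULT_TEXTURES",
    "make_synthetic_dataset",
    "stratified_split",
    "augment_batch",
    "save_image_folder",
    "load_image_folder",
    "build_tiny_teacher",
    "build_tiny_vit_student",
]

# (blob density in (0,1), blob radius px, blob RGB hue triple, pixel noise sd).
# Pairs of adjacent classes differ in only one or two parameters, so the class
# boundary is a texture-statistics boundary rather than a color-lookup one.
DEFAULT_TEXTURES: tuple = (
    (0.08, 2.5, (0.55, 0.25, 0.55), 0.05),
    (0.11, 2.5, (0.50, 0.22, 0.55), 0.05),
    (0.08, 3.5, (0.55, 0.25, 0.45), 0.05),
    (0.11, 3.5, (0.50, 0.22, 0.45), 0.05),
    (0.17, 2.0, (0.35, 0.15, 0.45), 0.06),
    (0.22, 2.0, (0.30, 0.15, 0.45), 0.06),
    (0.17, 3.0, (0.35, 0.12, 0.35), 0.06),
    (0.22, 3.0, (0.30, 0.12, 0.35), 0.06),
)

_BACKGROUND = np.array([0.82, 0.70, 0.80])  # eosin-pink base

# Fixed input-normalization constants for the synthetic world (the analog of
# the ImageNet mean/std used with real stained-tissue patches): reference
# channel statistics of the default generator, frozen once.
IMAGE_MEAN = np.array([0.594, 0.417, 0.607])
IMAGE_STD = np.array([0.174, 0.194, 0.146])


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    n_classes: int = 8
    n_per_class: int = 32
    image_size: int = 32
    texture_params: tuple = DEFAULT_TEXTURES
    seed: int = 0
    split_fractions: tuple = (0.6, 0.2, 0.2)

    def __post_init__(self):
        if self.n_classes < 2:
            raise InvalidSpecError("need at least 2 classes")
        if self.n_per_class < 4:
            raise InvalidSpecError("need at least 4 images per class")
        if self.image_size < 16:
            raise InvalidSpecError("image_size must be >= 16")
        if len(self.texture_params) < self.n_classes:
            raise InvalidSpecError(
                f"{self.n_classes} classes but only {len(self.texture_params)} texture tuples"
            )
        if abs(sum(self.split_fractions) - 1.0) > 1e-9 or min(self.split_fractions) < 0:
            raise InvalidSpecError("split fractions must be nonnegative and sum to 1")


@dataclass(frozen=True)
class ModelSpec:
    role: str  # "teacher" | "student"
    family: str  # "convolutional" | "transformer"
    depth: int = 4
    width: int = 32  # conv base channels / transformer embed dim
    patch_size: int = 8  # transformer only
    n_heads: int = 4  # transformer only
    n_classes: int = 8
    image_size: int = 32

    def __post_init__(self):
        if self.role not in ("teacher", "student"):
            raise InvalidSpecError(f"unknown role {self.role!r}")
        if self.family not in ("convolutional", "transformer"):
            raise InvalidSpecError(f"unknown family {self.family!r}")
        if self.depth < 3:
            raise InvalidSpecError("need depth >= 3 for a three-stage partition")
        if self.family == "transformer":
            if self.image_size % self.patch_size:
                raise InvalidSpecError(
                    f"image_size {self.image_size} not divisible by patch_size {self.patch_size}"
                )
            if self.width % self.n_heads:
                raise InvalidSpecError("embed dim must be divisible by n_heads")
        else:
            if self.image_size % (2**self.depth):
                raise InvalidSpecError(
                    f"image_size {self.image_size} not divisible by 2^depth"
                )

    @property
    def n_patch_tokens(self) -> int:
        return (self.image_size // self.patch_size) ** 2

    @property
    def seq_len(self) -> int:
        """Token count before distillation-token augmentation (CLS + patches)."""
        return self.n_patch_tokens + 1


def _render_image(size: int, params, rng: np.random.Generator) -> np.ndarray:
    density, radius, hue, noise_sd = params
    img = np.empty((size, size, 3))
    img[...] = _BACKGROUND
    # low-frequency background modulation (stain inhomogeneity)
    yy, xx = np.mgrid[0:size, 0:size] / size
    phase = rng.uniform(0, 2 * np.pi, size=2)
    wobble = 0.04 * np.sin(2 * np.pi * yy + phase[0]) * np.cos(2 * np.pi * xx + phase[1])
    img += wobble[..., None]

    n_blobs = max(1, int(round(density * (size / (2.0 * radius)) ** 2 * 4)))
    centers = rng.uniform(0, size, size=(n_blobs, 2))
    radii = radius * rng.uniform(0.7, 1.3, size=n_blobs)
    hue = np.asarray(hue)
    ygrid, xgrid = np.mgrid[0:size, 0:size]
    for (cy, cx), r in zip(centers, radii):
        d2 = (ygrid - cy) ** 2 + (xgrid - cx) ** 2
        profile = np.exp(-d2 / (2.0 * r * r))
        color = hue + rng.normal(0, 0.03, size=3)
        img = img * (1 - profile[..., None]) + profile[..., None] * color
    img += rng.normal(0, noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def augment_batch(images: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Mild stochastic augmentation: right-angle rotations, flips, brightness/
    color jitter and occasional light Gaussian blur. Deliberately gentle —
    stained-tissue textures are sensitive to aggressive transforms. Off by
    default in training configs so tests stay deterministic."""
    from scipy.ndimage import gaussian_filter

    out = np.empty_like(images)
    for i, img in enumerate(images):
        img = np.rot90(img, k=int(rng.integers(4)), axes=(0, 1))
        if rng.random() < 0.5:
            img = img[:, ::-1]
        if rng.random() < 0.5:
            img = img[::-1, :]
        img = img + rng.normal(0, 0.02) + rng.normal(0, 0.02, size=3)  # jitter
        if rng.random() < 0.25:
            img = gaussian_filter(img, sigma=(0.6, 0.6, 0.0))
        out[i] = np.clip(img, 0.0, 1.0)
    return out


def stratified_split(labels: np.ndarray, fractions=(0.6, 0.2, 0.2), seed: int = 0) -> dict:
    """Deterministic per-class train/val/test split (fractions of each class)."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    splits = {"train": [], "val": [], "test": []}
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = idx[rng.permutation(len(idx))]
        n = len(idx)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        splits["train"].extend(idx[:n_train])
        splits["val"].extend(idx[n_train : n_train + n_val])
        splits["test"].extend(idx[n_train + n_val :])
    return {k: np.sort(np.array(v, dtype=int)) for k, v in splits.items()}


def make_synthetic_dataset(spec: SyntheticDatasetSpec):
    """Generate (images, labels, split_indices).

    images: (N, size, size, 3) float64 in [0,1]; labels: (N,) int; splits are a
    dict of index arrays, stratified by class. Identical spec + seed gives a
    byte-identical dataset.
    """
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_classes * spec.n_per_class
    labels = np.repeat(np.arange(spec.n_classes), spec.n_per_class)
    images = np.empty((n_total, spec.image_size, spec.image_size, 3))
    for i, lab in enumerate(labels):
        images[i] = _render_image(spec.image_size, spec.texture_params[lab], rng)
    # shuffle so class blocks are interleaved, then split stratified
    perm = rng.permutation(n_total)
    images, labels = images[perm], labels[perm]
    splits = stratified_split(labels, spec.split_fractions, seed=spec.seed + 1)
    return images, labels, splits


def save_image_folder(images, labels, splits, out_dir) -> Path:
    """Write a class-per-folder PNG tree plus an index CSV (path,label,split)."""
    from PIL import Image

    out_dir = Path(out_dir)
    split_of = {}
    for name, idx in splits.items():
        for i in idx:
            split_of[int(i)] = name
    rows = []
    for i, (img, lab) in enumerate(zip(images, labels)):
        cls_dir = out_dir / f"class_{lab:02d}"
        cls_dir.mkdir(parents=True, exist_ok=True)
        path = cls_dir / f"img_{i:05d}.png"
        Image.fromarray((img * 255).round().astype(np.uint8)).save(path)
        rows.append((str(path.relative_to(out_dir)), int(lab), split_of.get(i, "train")))
    with open(out_dir / "index.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "label", "split"])
        writer.writerows(rows)
    return out_dir


def load_image_folder(root) -> tuple:
    """Read a class-per-folder tree written by :func:`save_image_folder`.

    Returns (images, labels, splits); uses index.csv when present, otherwise
    infers labels from folder names and puts everything in "train".
    """
    from PIL import Image

    root = Path(root)
    index = root / "index.csv"
    images, labels, split_names = [], [], []
    if index.exists():
        with open(index) as fh:
            for row in csv.DictReader(fh):
                images.append(np.asarray(Image.open(root / row["path"])) / 255.0)
                labels.append(int(row["label"]))
                split_names.append(row["split"])
    else:
        for k, cls_dir in enumerate(sorted(p for p in root.iterdir() if p.is_dir())):
            for path in sorted(cls_dir.glob("*.png")):
                images.append(np.asarray(Image.open(path)) / 255.0)
                labels.append(k)
                split_names.append("train")
    images = np.stack(images)
    labels = np.asarray(labels)
    split_names = np.asarray(split_names)
    splits = {name: np.flatnonzero(split_names == name) for name in ("train", "val", "test")}
    return images, labels, splits


def build_tiny_teacher(spec: ModelSpec):
    """Construct the convolutional teacher described by `spec`."""
    if spec.family != "convolutional":
        raise InvalidSpecError("teacher builder expects a convolutional spec")
    from .models import TinyConvNet

    return TinyConvNet(spec)


def build_tiny_vit_student(spec: ModelSpec):
    """Construct the transformer student described by `spec`."""
    if spec.family != "transformer":
        raise InvalidSpecError("student builder expects a transformer spec")
    from .models import TinyViT

    return TinyViT(spec)
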