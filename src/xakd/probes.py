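"""Per-layer summary representations, stage partitions, attention maps.

Transformer layers are summarized by the CLS token state and convolutional
layers by global average pooling, so every probe point yields an
(n samples x d features) matrix regardless of architecture — the common
currency for CKA/KCCA layer comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import zoom

from .errors import PartitionError, ProbeError
from .nn import Tensor, no_grad

__all__ = [
    "RepresentationMatrix",
    "StagePartition",
    "AttentionMap",
    "gap",
    "capture_representations",
    "partition_stages",
    "extract_attention_map",
    "save_representations",
]

STAGE_NAMES = ("early", "mid", "late")


@dataclass
class RepresentationMatrix:
    values: np.ndarray  # (n samples, d features)
    layer_id: int
    model_role: str  # "teacher" | "student"
    summary_kind: str  # "cls" | "gap"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ProbeError("representation must be a 2-D (samples x features) matrix")
        if self.values.shape[0] < 4:
            raise ProbeError("need n >= 4 samples (unbiased HSIC denominator n(n-3))")
        if not np.all(np.isfinite(self.values)):
            raise ProbeError(f"non-finite values in representation of layer {self.layer_id}")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class StagePartition:
    """Ordered (early, mid, late) contiguous, disjoint layer-index ranges."""

    stages: tuple  # tuple of 3 tuples of layer indices

    def __post_init__(self):
        flat = [i for stage in self.stages for i in stage]
        if len(self.stages) < 1 or any(len(s) == 0 for s in self.stages):
            raise PartitionError("every stage must be non-empty")
        if flat != sorted(set(flat)) or flat != list(range(len(flat))):
            raise PartitionError("stages must cover 0..n_layers-1 exactly once, in order")

    def __iter__(self):
        return iter(self.stages)

    def __getitem__(self, i):
        return self.stages[i]

    @property
    def n_layers(self) -> int:
        return sum(len(s) for s in self.stages)


@dataclass
class AttentionMap:
    grid: np.ndarray  # (g, g), values in [0,1]
    overlay: np.ndarray  # grid bilinearly upsampled to input resolution

    def __post_init__(self):
        if self.grid.min() < -1e-12 or self.grid.max() > 1 + 1e-12:
            raise ProbeError("attention grid must be normalized to [0,1]")


def gap(feature_map: np.ndarray) -> np.ndarray:
    """Global average pooling: (n, C, H, W) -> (n, C) spatial mean."""
    feature_map = np.asarray(feature_map, dtype=float)
    if feature_map.ndim != 4:
        raise ProbeError("GAP expects an (n, C, H, W) feature map")
    return feature_map.mean(axis=(2, 3))


def capture_representations(model, batch, probe_points=None) -> list:
    """Run `batch` through `model` and summarize every probe point.

    CNN probe points (4-D feature maps) are summarized by GAP; transformer
    probe points (token sequences) by the CLS token state. Distillation-token
    slots, if present, are excluded by construction (CLS is slot 0).
    """
    batch = np.asarray(batch)
    if batch.shape[0] < 4:
        raise ProbeError("probing batch must contain at least 4 samples")
    names = list(model.probe_points) if probe_points is None else list(probe_points)
    unknown = set(names) - set(model.probe_points)
    if unknown:
        raise ProbeError(f"unknown probe points: {sorted(unknown)}")
    role = model.spec.role
    with no_grad():
        _, feats = model.forward_features(batch)
    out = []
    for layer_id, name in enumerate(names):
        act = feats[name]
        arr = act.data if isinstance(act, Tensor) else np.asarray(act)
        if arr.ndim == 4:
            out.append(RepresentationMatrix(gap(arr), layer_id, role, "gap"))
        elif arr.ndim == 3:  # (n, tokens, d): CLS summary
            out.append(RepresentationMatrix(arr[:, 0, :], layer_id, role, "cls"))
        else:
            raise ProbeError(f"cannot summarize activation of ndim {arr.ndim}")
    return out


def partition_stages(n_layers: int, n_stages: int = 3) -> StagePartition:
    """Uniform partition of layer indices into contiguous stages of near-equal
    depth; remainder layers go to the earliest stages."""
    if n_layers < n_stages:
        raise PartitionError(f"cannot split {n_layers} layers into {n_stages} stages")
    base, rem = divmod(n_layers, n_stages)
    sizes = [base + (1 if i < rem else 0) for i in range(n_stages)]
    stages, start = [], 0
    for s in sizes:
        stages.append(tuple(range(start, start + s)))
        start += s
    return StagePartition(tuple(stages))


def extract_attention_map(model, image) -> AttentionMap:
    """CLS-row attention of the final transformer block for a single image.

    Per head: take the CLS query row, drop the CLS->CLS entry and any
    distillation-token columns, reshape the patch entries to a g x g grid.
    Heads are averaged, min-max normalized (an all-equal map maps to zeros),
    and bilinearly upsampled to the input resolution.
    """
    if not hasattr(model, "final_attention"):
        raise ProbeError("attention extraction requires a transformer model")
    image = np.asarray(image)
    if image.ndim == 3:
        image = image[None]
    with no_grad():
        model.forward_features(image, capture_attention=True)
    attn = model.final_attention()[0]  # (H, T, T)
    n_patch = model.spec.n_patch_tokens
    g = int(np.sqrt(n_patch))
    cls_rows = attn[:, 0, 1 : 1 + n_patch]  # drop CLS->CLS; trailing distill cols excluded
    mean_map = cls_rows.mean(axis=0).reshape(g, g)
    lo, hi = mean_map.min(), mean_map.max()
    grid = np.zeros_like(mean_map) if hi - lo < 1e-12 else (mean_map - lo) / (hi - lo)
    scale = image.shape[1] / g
    overlay = zoom(grid, scale, order=1, grid_mode=True, mode="nearest")
    return AttentionMap(grid=grid, overlay=overlay)


def save_representations(reps: list, out_dir) -> Path:
    """One CSV per probe point plus a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for rep in reps:
        fname = f"{rep.model_role}_layer{rep.layer_id:02d}.csv"
        np.savetxt(out_dir / fname, rep.values, delimiter=",")
        manifest.append(
            {
                "file": fname,
                "layer_id": rep.layer_id,
                "model_role": rep.model_role,
                "summary_kind": rep.summary_kind,
                "shape": list(rep.values.shape),
            }
        )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir
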