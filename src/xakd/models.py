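"""Desk-scale teacher/student architectures with named probe points.

`TinyConvNet` is a small VGG-style stack of conv/ReLU/pool stages with a
global-average-pool head; `TinyViT` is a standard pre-norm vision transformer
with a CLS token. Both expose `probe_points` (ordered layer names) and a
`forward_features` pass that returns the raw activation at every probe point,
which is what the similarity/matching machinery consumes.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .errors import InvalidSpecError, ProbeError
from .fixtures import IMAGE_MEAN, IMAGE_STD, ModelSpec
from .nn import functional as F


def _normalize(images: np.ndarray) -> np.ndarray:
    """Standardize channels with the fixed dataset constants (the analog of
    ImageNet mean/std normalization in the training protocol)."""
    return (np.asarray(images) - IMAGE_MEAN) / IMAGE_STD


def _to_nchw(images: np.ndarray) -> np.ndarray:
    """(N,H,W,3) float images -> (N,3,H,W)."""
    return np.ascontiguousarray(np.transpose(images, (0, 3, 1, 2)))


class TinyConvNet(nn.Module):
    """Convolutional classifier: `depth` stages of conv3x3 -> ReLU -> avgpool2.

    Probe point i ("stage{i}") is the post-activation feature map of stage i,
    shape (N, C_i, H_i, W_i) — the tensor the AE projectors pool over.
    """

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.channels = [min(spec.width * 2**i, spec.width * 4) for i in range(spec.depth)]
        c_in = 3
        self.convs, self.norms = [], []
        for c_out in self.channels:
            self.convs.append(nn.Conv2d(c_in, c_out, k=3, stride=1, pad=1, rng=rng))
            self.norms.append(nn.ChannelNorm(c_out))
            c_in = c_out
        self.head = nn.Linear(c_in, spec.n_classes, rng=rng)
        self.probe_points = [f"stage{i}" for i in range(spec.depth)]

    def forward_features(self, x):
        if not isinstance(x, nn.Tensor):
            x = nn.Tensor(_to_nchw(_normalize(x)))
        feats = {}
        for i, (conv, norm) in enumerate(zip(self.convs, self.norms)):
            x = norm(conv(x)).relu()
            feats[f"stage{i}"] = x
            x = F.avg_pool2d(x, 2)
        logits = self.head(F.global_avg_pool(x))
        return logits, feats

    def forward(self, x):
        return self.forward_features(x)[0]


class TinyViT(nn.Module):
    """Pre-norm ViT classifier with CLS token and learnable position embeddings.

    Probe point i ("block{i}") is the full token sequence after block i.
    `extra_tokens` (a (k, D) parameter) are appended after the patch tokens
    with their own positional entries; the classifier head reads CLS only, so
    appended tokens change logits only through attention mixing.
    """

    def __init__(self, spec: ModelSpec, seed: int = 0):
        if spec.family != "transformer":
            raise InvalidSpecError("TinyViT requires a transformer spec")
        self.spec = spec
        rng = np.random.default_rng(seed)
        d = spec.width
        self.patch_dim = 3 * spec.patch_size**2
        self.patch_embed = nn.Linear(self.patch_dim, d, rng=rng)
        self.cls_token = nn.Parameter(rng.normal(0, 0.02, size=(1, 1, d)))
        self.pos_embed = nn.Parameter(rng.normal(0, 0.02, size=(spec.seq_len, d)))
        self.blocks = [
            nn.TransformerBlock(d, spec.n_heads, mlp_ratio=2, rng=rng)
            for _ in range(spec.depth)
        ]
        self.norm = nn.LayerNorm(d)
        self.head = nn.Linear(d, spec.n_classes, rng=rng)
        self.probe_points = [f"block{i}" for i in range(spec.depth)]

    def _patchify(self, images: np.ndarray) -> np.ndarray:
        n, h, w, _ = images.shape
        ps = self.spec.patch_size
        g = h // ps
        x = images.reshape(n, g, ps, g, ps, 3)
        return x.transpose(0, 1, 3, 2, 4, 5).reshape(n, g * g, self.patch_dim)

    def forward_features(self, x, extra_tokens=None, extra_pos=None,
                         capture_attention: bool = False):
        """Return (logits, {probe: token sequence (N, T, D)}).

        When `extra_tokens`/`extra_pos` are given (shape (k, D)), the k tokens
        are appended after the patch tokens before block 0.
        """
        if not isinstance(x, nn.Tensor):
            x = nn.Tensor(self._patchify(_normalize(x)))
        n = x.shape[0]
        tokens = self.patch_embed(x)
        cls = self.cls_token + nn.Tensor(np.zeros((n, 1, tokens.shape[-1])))
        seq = nn.concat([cls, tokens], axis=1)
        pos = self.pos_embed
        if extra_tokens is not None:
            k = extra_tokens.shape[0]
            extras = extra_tokens.reshape(1, k, -1) + nn.Tensor(
                np.zeros((n, k, tokens.shape[-1]))
            )
            seq = nn.concat([seq, extras], axis=1)
            pos = nn.concat([pos, extra_pos], axis=0)
        seq = seq + pos
        feats = {}
        last = len(self.blocks) - 1
        for i, block in enumerate(self.blocks):
            seq = block(seq, capture_attention=capture_attention and i == last)
            feats[f"block{i}"] = seq
        logits = self.head(self.norm(seq[:, 0, :]))
        return logits, feats

    def forward(self, x):
        return self.forward_features(x)[0]

    def final_attention(self) -> np.ndarray:
        """Attention tensor (N, H, T, T) of the last block's most recent
        capture-enabled forward pass."""
        attn = self.blocks[-1].attn.last_attention
        if attn is None:
            raise ProbeError("no attention captured; run forward_features(capture_attention=True)")
        return attn
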