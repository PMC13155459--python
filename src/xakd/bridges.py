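"""Stage-level feature-distillation pathways.

Student side: three learnable distillation tokens appended to the ViT token
sequence (after the patch tokens), each read out at its bridge layer's depth
but propagated through all blocks, so the computation graph of the base model
is unchanged apart from sequence length. Teacher side: one autoencoder
projector per bridge pair mapping the pooled teacher feature map (C channels)
through a 512-wide hidden layer to the student token dimension D, with a
mirrored decoder whose reconstruction loss keeps the latent informative. The
alignment signal is a scale-invariant cosine loss between each projector
latent and its distillation token state.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .errors import ConfigError, DegenerateDataError, ValidationError
from .nn import Tensor
from .nn import functional as F

__all__ = [
    "DistillationTokenBank",
    "AeProjector",
    "AugmentedStudent",
    "augment_student_tokens",
    "extract_token_states",
    "ae_forward",
    "cosine_feature_loss",
    "recon_loss",
    "stage_feature_loss",
]

N_STAGES = 3


class DistillationTokenBank(nn.Module):
    """Three stage tokens + their positional-embedding extension entries."""

    def __init__(self, embed_dim: int, extraction_depths, n_layers: int, seed: int = 0):
        depths = [int(d) for d in extraction_depths]
        if len(depths) != N_STAGES:
            raise ConfigError(f"need exactly {N_STAGES} extraction depths")
        if any(d < 0 or d >= n_layers for d in depths):
            raise ConfigError(f"extraction depths {depths} outside 0..{n_layers - 1}")
        rng = np.random.default_rng(seed)
        # small-scale normal like patch embeddings; positional entries start at 0
        self.tokens = nn.Parameter(rng.normal(0.0, 0.02, size=(N_STAGES, embed_dim)))
        self.pos_ext = nn.Parameter(np.zeros((N_STAGES, embed_dim)))
        self.extraction_depths = depths


class AugmentedStudent(nn.Module):
    """A ViT student with the token bank appended to every forward pass."""

    def __init__(self, student, bank: DistillationTokenBank):
        if isinstance(student, AugmentedStudent):
            raise ConfigError("student is already token-augmented")
        self.student = student
        self.bank = bank
        self.spec = student.spec
        self.probe_points = student.probe_points

    @property
    def seq_len(self) -> int:
        return self.student.spec.seq_len + N_STAGES

    def forward_features(self, x, capture_attention: bool = False):
        return self.student.forward_features(
            x,
            extra_tokens=self.bank.tokens,
            extra_pos=self.bank.pos_ext,
            capture_attention=capture_attention,
        )

    def forward(self, x):
        return self.forward_features(x)[0]

    def final_attention(self):
        return self.student.final_attention()


def augment_student_tokens(student, bank: DistillationTokenBank) -> AugmentedStudent:
    """Attach the token bank; re-augmenting an augmented model is an error."""
    if bank.tokens.shape[1] != student.spec.width:
        raise ConfigError(
            f"token dim {bank.tokens.shape[1]} != student embed dim {student.spec.width}"
        )
    return AugmentedStudent(student, bank)


def extract_token_states(model: AugmentedStudent, feats: dict | None = None, batch=None):
    """Per-stage distillation-token states, each (batch, D).

    Stage s is read from token slot (base_seq_len + s) after the block at its
    extraction depth. Pass the `feats` dict of a forward pass to reuse its
    graph (training), or `batch` to run a fresh pass.
    """
    if feats is None:
        if batch is None:
            raise ConfigError("provide either a feats dict or a batch")
        _, feats = model.forward_features(batch)
    base = model.student.spec.seq_len
    states = []
    for s, depth in enumerate(model.bank.extraction_depths):
        name = f"block{depth}"
        if name not in feats:
            raise ConfigError(f"extraction depth {depth} outside the model")
        states.append(feats[name][:, base + s, :])
    return states


class AeProjector(nn.Module):
    """Pool -> C->512 -> LayerNorm -> GELU -> 512->D encoder with a mirrored
    decoder D->512->C reconstructing the pooled vector."""

    def __init__(self, in_channels: int, latent_dim: int = 192, hidden: int = 512, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.in_channels = int(in_channels)
        self.latent_dim = int(latent_dim)
        self.enc1 = nn.Linear(in_channels, hidden, rng=rng)
        self.enc_norm = nn.LayerNorm(hidden)
        self.enc2 = nn.Linear(hidden, latent_dim, rng=rng)
        self.dec1 = nn.Linear(latent_dim, hidden, rng=rng)
        self.dec_norm = nn.LayerNorm(hidden)
        self.dec2 = nn.Linear(hidden, in_channels, rng=rng)

    def encode(self, f: Tensor) -> Tensor:
        return self.enc2(self.enc_norm(self.enc1(f)).gelu())

    def decode(self, z: Tensor) -> Tensor:
        return self.dec2(self.dec_norm(self.dec1(z)).gelu())


def ae_forward(proj: AeProjector, feature_map):
    """(v, f, f_hat): latent, pooled teacher vector, reconstruction.

    `feature_map` is a (batch, C, H, W) teacher activation; it is treated as a
    constant (teacher gradients do not flow through the projector pathway).
    """
    arr = feature_map.data if isinstance(feature_map, Tensor) else np.asarray(feature_map)
    if arr.ndim != 4:
        raise ValidationError("expected a (batch, C, H, W) feature map")
    if arr.shape[1] != proj.in_channels:
        raise ValidationError(
            f"feature map has {arr.shape[1]} channels, projector expects {proj.in_channels}"
        )
    f = Tensor(arr.mean(axis=(2, 3)))  # GAP, constant target
    v = proj.encode(f)
    f_hat = proj.decode(v)
    return v, f, f_hat


def cosine_feature_loss(v, t):
    """1 - cos(v, t), batch-averaged; in [0, 2] and invariant to positive
    rescaling of either argument."""
    v = v if isinstance(v, Tensor) else Tensor(np.asarray(v, dtype=float))
    t = t if isinstance(t, Tensor) else Tensor(np.asarray(t, dtype=float))
    if v.shape[-1] != t.shape[-1]:
        raise ValidationError("vectors must share their last dimension")
    nv = (v**2).sum(axis=-1).sqrt()
    nt = (t**2).sum(axis=-1).sqrt()
    if np.any(nv.data < 1e-12) or np.any(nt.data < 1e-12):
        raise DegenerateDataError("cosine loss undefined for zero-norm vectors")
    cos = (v * t).sum(axis=-1) / (nv * nt)
    loss = 1.0 - cos
    return loss.mean() if loss.ndim else loss


def recon_loss(f, f_hat):
    """Mean squared error between the pooled vector and its reconstruction."""
    f = f if isinstance(f, Tensor) else Tensor(np.asarray(f, dtype=float))
    f_hat = f_hat if isinstance(f_hat, Tensor) else Tensor(np.asarray(f_hat, dtype=float))
    if f.shape != f_hat.shape:
        raise ValidationError(f"shape mismatch {f.shape} vs {f_hat.shape}")
    return ((f - f_hat) ** 2).mean()


def stage_feature_loss(stage_losses, stage_weights):
    """Weighted sum over (early, mid, late); weights are binary in the three
    stated configurations but any nonnegative reals are accepted."""
    stage_losses = list(stage_losses)
    stage_weights = list(stage_weights)
    if len(stage_losses) != N_STAGES or len(stage_weights) != N_STAGES:
        raise ValidationError(f"need {N_STAGES} stage losses and weights")
    total = 0.0
    for loss, w in zip(stage_losses, stage_weights):
        total = total + float(w) * loss
    return total
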