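"""Response distillation and the composite training objective.

Response KD is the temperature-softened KL divergence between teacher and
student logits, KL(softmax(z_t/T) || softmax(z_s/T)) * T^2 (teacher first;
the T^2 factor restores gradient magnitude). The total objective is

    L_total = alpha * L_cls + (1 - alpha) * L_kd
              + gamma * (L_feat + lambda_recon * L_recon).

alpha, gamma, T are not stated in the source protocol; the defaults here
(alpha=0.5, T=4, gamma=1, lambda_recon=1) are package choices, exposed in the
run config.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .nn import Tensor
from .nn import functional as F

__all__ = ["LossWeights", "LossBreakdown", "soften", "response_kd_loss", "total_loss"]


@dataclass(frozen=True)
class LossWeights:
    alpha: float = 0.5  # CE vs response-KD balance, in [0,1]
    gamma: float = 1.0  # weight of the feature-distillation block
    temperature: float = 4.0
    lambda_recon: float = 1.0
    stage_weights: tuple = (1, 1, 0)  # (early, mid, late); primary preset

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError("alpha must lie in [0, 1]")
        if self.gamma < 0:
            raise ValidationError("gamma must be nonnegative")
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")


STAGE_WEIGHT_PRESETS = {
    "early_mid": (1, 1, 0),  # primary setting
    "mid_late": (0, 1, 1),
    "all": (1, 1, 1),
}


def _as_float(x) -> float:
    return float(x.data) if isinstance(x, Tensor) else float(x)


@dataclass
class LossBreakdown:
    l_cls: float
    l_kd: float
    l_feat_stages: tuple  # per-stage cosine losses (early, mid, late)
    l_feat: float  # stage-weighted sum
    l_recon: float
    l_total: float
    weights: LossWeights

    def recompute_total(self) -> float:
        w = self.weights
        return (
            w.alpha * self.l_cls
            + (1 - w.alpha) * self.l_kd
            + w.gamma * (self.l_feat + w.lambda_recon * self.l_recon)
        )


def soften(z, T: float):
    """Temperature-softened softmax exp(z_i/T) / sum_j exp(z_j/T).

    Accepts a logit vector or a (batch, classes) array; computed with
    max-subtraction stability. Returns an array of the same shape.
    """
    if T <= 0:
        raise ValidationError("temperature must be positive")
    z = np.asarray(z, dtype=float)
    return np.asarray(F.softmax(Tensor(z) * (1.0 / T), axis=-1))


def response_kd_loss(z_t, z_s, T: float):
    """KL(softened teacher || softened student) * T^2, batch mean.

    `z_t` is treated as a constant target; gradients flow only through `z_s`
    when it is a graph Tensor.
    """
    if T <= 0:
        raise ValidationError("temperature must be positive")
    zt = np.asarray(z_t, dtype=float)
    zs = z_s if isinstance(z_s, Tensor) else Tensor(np.asarray(z_s, dtype=float))
    if zt.shape[-1] != zs.shape[-1]:
        raise ValidationError("teacher and student must have the same class count")
    invT = 1.0 / T
    pt = np.asarray(F.softmax(Tensor(zt * invT), axis=-1))
    log_pt = np.asarray(F.log_softmax(Tensor(zt * invT), axis=-1))
    log_ps = F.log_softmax(zs * invT, axis=-1)
    kl_per_sample = (Tensor(pt) * (Tensor(log_pt) - log_ps)).sum(axis=-1)
    loss = kl_per_sample.mean() * (T * T) if kl_per_sample.ndim else kl_per_sample * (T * T)
    return loss


def total_loss(l_cls, l_kd, l_feat, l_recon, weights: LossWeights):
    """Compose the training objective.

    Scalar parts may be graph Tensors (training) or floats (analysis). Returns
    (total, LossBreakdown) where `total` preserves the graph and the breakdown
    records float values satisfying the recomposition invariant.
    """
    parts = {"l_cls": l_cls, "l_kd": l_kd, "l_feat": l_feat, "l_recon": l_recon}
    for name, p in parts.items():
        if not np.isfinite(_as_float(p)):
            raise ValidationError(f"non-finite loss term {name}")
    w = weights
    total = (
        w.alpha * l_cls
        + (1 - w.alpha) * l_kd
        + w.gamma * (l_feat + w.lambda_recon * l_recon)
    )
    breakdown = LossBreakdown(
        l_cls=_as_float(l_cls),
        l_kd=_as_float(l_kd),
        l_feat_stages=(),
        l_feat=_as_float(l_feat),
        l_recon=_as_float(l_recon),
        l_total=_as_float(total),
        weights=w,
    )
    return total, breakdown
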