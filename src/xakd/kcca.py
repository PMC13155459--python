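"""Regularized kernel canonical correlation analysis between two layers.

Given centered Gram matrices K_X, K_Y of the same n samples under (by default
RBF) kernels, KCCA maximizes corr(a'K_X, b'K_Y) subject to the ridge-softened
normalizations a'(K_X + kI)K_X a = b'(K_Y + kI)K_Y b = 1. Because a centered
Gram matrix commutes with itself, each quadratic form M = K^2 + kK is
symmetric PSD, so the problem reduces to the SVD of the whitened cross-product

    C = M_X^{-1/2} K_X K_Y M_Y^{-1/2},

whose singular values are the canonical correlations rho_1 >= rho_2 >= ...
The scalar compatibility score is rho_bar, the mean of the top-m correlations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import DegenerateDataError, NumericalError, ValidationError
from .similarity import GramMatrix, _rep_values

__all__ = [
    "KccaConfig",
    "KccaResult",
    "rbf_gram",
    "linear_gram",
    "median_bandwidth",
    "center_gram",
    "kcca_correlations",
    "mean_top_m",
    "kcca_rho_bar",
]


@dataclass(frozen=True)
class KccaConfig:
    kernel: str = "rbf"  # "rbf" | "linear"
    bandwidth: float | None = None  # None -> median heuristic, per view
    kappa: float = 1e-4  # absolute ridge on the Gram matrix
    m: int = 10  # number of leading correlations in rho_bar
    clip: bool = True  # clip round-off correlations into [0,1]

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValidationError("ridge kappa must be positive")
        if self.m < 1:
            raise ValidationError("m must be >= 1")
        if self.kernel not in ("rbf", "linear"):
            raise ValidationError(f"unknown kernel {self.kernel!r}")


@dataclass
class KccaResult:
    correlations: np.ndarray  # descending
    rho_bar: float
    kappa: float
    bandwidths: tuple = (None, None)

    def to_json(self) -> str:
        return json.dumps(
            {
                "correlations": [float(r) for r in self.correlations],
                "rho_bar": float(self.rho_bar),
                "kappa": self.kappa,
                "bandwidths": [None if b is None else float(b) for b in self.bandwidths],
            },
            indent=2,
        )


def median_bandwidth(X) -> float:
    """Median of the nonzero pairwise Euclidean distances (RBF sigma)."""
    X = _rep_values(X)
    d = pdist(X)
    d = d[d > 0]
    if d.size == 0:
        raise DegenerateDataError("all points identical; RBF bandwidth undefined")
    return float(np.median(d))


def rbf_gram(X, bandwidth: float | None = None) -> GramMatrix:
    """RBF Gram matrix exp(-||xi - xj||^2 / (2 sigma^2)); sigma defaults to the
    median heuristic. Diagonal is exactly 1."""
    X = _rep_values(X)
    if X.shape[0] < 4:
        raise ValidationError("need n >= 4 samples")
    sigma = median_bandwidth(X) if bandwidth is None else float(bandwidth)
    if sigma <= 0:
        raise DegenerateDataError("bandwidth must be positive")
    sq = squareform(pdist(X, "sqeuclidean"))
    K = np.exp(-sq / (2.0 * sigma**2))
    np.fill_diagonal(K, 1.0)
    return GramMatrix(K, kernel_kind="rbf", state="raw")


def linear_gram(X) -> GramMatrix:
    X = _rep_values(X)
    return GramMatrix(X @ X.T, kernel_kind="linear", state="raw")


def center_gram(K: GramMatrix) -> GramMatrix:
    """Double centering HKH with H = I - (1/n) 11'; idempotent."""
    arr = K.values if isinstance(K, GramMatrix) else np.asarray(K, dtype=float)
    n = arr.shape[0]
    row = arr.mean(axis=0, keepdims=True)
    col = arr.mean(axis=1, keepdims=True)
    centered = arr - row - col + arr.mean()
    kind = K.kernel_kind if isinstance(K, GramMatrix) else "linear"
    return GramMatrix(centered, kernel_kind=kind, state="centered")


def _inv_sqrt_psd(M: np.ndarray, rcond: float = 1e-12) -> np.ndarray:
    """Pseudo-inverse square root of a symmetric PSD matrix."""
    w, V = np.linalg.eigh((M + M.T) / 2.0)
    if not np.all(np.isfinite(w)):
        raise NumericalError("eigensolve returned non-finite eigenvalues")
    wmax = max(w.max(), 0.0)
    keep = w > rcond * max(wmax, 1.0)
    inv_sqrt = np.zeros_like(w)
    inv_sqrt[keep] = 1.0 / np.sqrt(w[keep])
    return (V * inv_sqrt) @ V.T


def kcca_correlations(KX, KY, cfg: KccaConfig = KccaConfig()) -> KccaResult:
    """Canonical correlations of two centered Gram matrices (see module doc)."""
    KXv = KX.values if isinstance(KX, GramMatrix) else np.asarray(KX, dtype=float)
    KYv = KY.values if isinstance(KY, GramMatrix) else np.asarray(KY, dtype=float)
    if KXv.shape != KYv.shape or KXv.shape[0] != KXv.shape[1]:
        raise ValidationError("centered Gram matrices must be square and share n")
    k = cfg.kappa
    MX = KXv @ KXv + k * KXv
    MY = KYv @ KYv + k * KYv
    WX, WY = _inv_sqrt_psd(MX), _inv_sqrt_psd(MY)
    C = WX @ KXv @ KYv @ WY
    s = np.linalg.svd(C, compute_uv=False)
    if not np.all(np.isfinite(s)):
        raise NumericalError(
            f"non-finite canonical correlations (cond MX={np.linalg.cond(MX):.2e})"
        )
    s = np.sort(s)[::-1]
    if cfg.clip:
        s = np.clip(s, 0.0, 1.0)
    return KccaResult(correlations=s, rho_bar=mean_top_m(s, cfg.m), kappa=k)


def mean_top_m(correlations, m: int) -> float:
    """Mean of the min(m, available) largest canonical correlations."""
    corr = np.asarray(
        correlations.correlations if isinstance(correlations, KccaResult) else correlations,
        dtype=float,
    )
    if corr.size == 0:
        raise ValidationError("empty correlation list")
    if m < 1:
        raise ValidationError("m must be >= 1")
    top = np.sort(corr)[::-1][: min(m, corr.size)]
    return float(top.mean())


def kcca_rho_bar(X, Y, cfg: KccaConfig = KccaConfig()) -> KccaResult:
    """End-to-end convenience: representations -> kernels -> centered Grams ->
    canonical correlations -> rho_bar."""
    if cfg.kernel == "rbf":
        bx = cfg.bandwidth if cfg.bandwidth is not None else median_bandwidth(X)
        by = cfg.bandwidth if cfg.bandwidth is not None else median_bandwidth(Y)
        KX, KY = rbf_gram(X, bx), rbf_gram(Y, by)
        bands = (bx, by)
    else:
        KX, KY = linear_gram(X), linear_gram(Y)
        bands = (None, None)
    result = kcca_correlations(center_gram(KX), center_gram(KY), cfg)
    result.bandwidths = bands
    return result
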