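"""Unbiased HSIC and linear CKA between layer representations.

The HSIC estimator is the unbiased three-term form on diagonal-zeroed Gram
matrices:

    HSIC(K, L) = [ tr(K~ L~) + (1'K~1)(1'L~1)/((n-1)(n-2)) - 2/(n-2) 1'K~L~1 ]
                 / (n(n-3))

with K~, L~ the Gram matrices with zeroed diagonals. CKA normalizes by the
square root of the two self-HSIC terms, bounding similarity by 1 and making it
invariant to isotropic scaling and orthogonal transforms of either
representation. Slightly negative values (unbiasedness at small n) are kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DegenerateDataError, ValidationError
from .probes import RepresentationMatrix

__all__ = [
    "GramMatrix",
    "CkaMatrix",
    "unbiased_hsic",
    "linear_cka",
    "minibatch_cka",
    "stage_cka_matrix",
    "save_cka_matrix",
]

_SYM_TOL = 1e-8


@dataclass
class GramMatrix:
    values: np.ndarray
    kernel_kind: str = "linear"  # "linear" | "rbf"
    state: str = "raw"  # "raw" | "diag_zeroed" | "centered"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("Gram matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValidationError("Gram matrix has non-finite entries")
        if np.max(np.abs(v - v.T)) > _SYM_TOL * max(1.0, np.max(np.abs(v))):
            raise ValidationError("Gram matrix is not symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class CkaMatrix:
    """Pairwise CKA between the teacher/student layers of one paired stage."""

    values: np.ndarray  # (|teacher stage|, |student stage|)
    teacher_layers: tuple
    student_layers: tuple
    stage: str
    batch_size: int


def _as_gram(K) -> np.ndarray:
    arr = K.values if isinstance(K, GramMatrix) else np.asarray(K, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValidationError("Gram matrix must be square")
    if np.max(np.abs(arr - arr.T)) > _SYM_TOL * max(1.0, np.max(np.abs(arr))):
        raise ValidationError("Gram matrix is not symmetric")
    return arr


def unbiased_hsic(K, L) -> float:
    """Unbiased HSIC estimator on two n x n Gram matrices (n >= 4)."""
    K, L = _as_gram(K), _as_gram(L)
    n = K.shape[0]
    if L.shape[0] != n:
        raise ValidationError("Gram matrices must share n")
    if n < 4:
        raise ValidationError("unbiased HSIC requires n >= 4")
    Kt = K - np.diag(np.diag(K))
    Lt = L - np.diag(np.diag(L))
    term1 = np.sum(Kt * Lt)  # tr(K~ L~) since both symmetric
    term2 = Kt.sum() * Lt.sum() / ((n - 1) * (n - 2))
    term3 = 2.0 / (n - 2) * (Kt.sum(axis=0) @ Lt.sum(axis=1))
    return float((term1 + term2 - term3) / (n * (n - 3)))


def _rep_values(X) -> np.ndarray:
    if isinstance(X, RepresentationMatrix):
        return X.values
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("representation must be 2-D (samples x features)")
    return arr


def linear_cka(X, Y) -> float:
    """Linear CKA between (n x d_x) and (n x d_y) representations."""
    X, Y = _rep_values(X), _rep_values(Y)
    if X.shape[0] != Y.shape[0]:
        raise ValidationError("representations must share the sample axis")
    K, L = X @ X.T, Y @ Y.T
    hkk, hll = unbiased_hsic(K, K), unbiased_hsic(L, L)
    if hkk <= 0 or hll <= 0:
        raise DegenerateDataError(
            "zero/negative self-HSIC: representation is (near-)constant; "
            "CKA is undefined for this input"
        )
    return unbiased_hsic(K, L) / np.sqrt(hkk * hll)


def minibatch_cka(X_batches, Y_batches) -> float:
    """Minibatch CKA: accumulate HSIC terms over aligned batch pairs, then
    normalize once by the square root of the accumulated self-terms."""
    X_batches, Y_batches = list(X_batches), list(Y_batches)
    if len(X_batches) != len(Y_batches) or not X_batches:
        raise ValidationError("need k >= 1 aligned batch pairs")
    num = skk = sll = 0.0
    for Xb, Yb in zip(X_batches, Y_batches):
        Xb, Yb = _rep_values(Xb), _rep_values(Yb)
        if Xb.shape[0] != Yb.shape[0]:
            raise ValidationError("batch pair has mismatched sample counts")
        K, L = Xb @ Xb.T, Yb @ Yb.T
        num += unbiased_hsic(K, L)
        skk += unbiased_hsic(K, K)
        sll += unbiased_hsic(L, L)
    if skk <= 0 or sll <= 0:
        raise DegenerateDataError("accumulated self-HSIC non-positive")
    return float(num / np.sqrt(skk * sll))


def stage_cka_matrix(teacher_reps, student_reps, t_stage, s_stage, stage: str = "") -> CkaMatrix:
    """All pairwise CKA values between the teacher layers `t_stage` and the
    student layers `s_stage` (layer indices into the probing runs)."""
    t_stage, s_stage = tuple(t_stage), tuple(s_stage)
    n = teacher_reps[t_stage[0]].n if isinstance(teacher_reps[t_stage[0]], RepresentationMatrix) else len(_rep_values(teacher_reps[t_stage[0]]))
    vals = np.empty((len(t_stage), len(s_stage)))
    for a, ti in enumerate(t_stage):
        for b, sj in enumerate(s_stage):
            try:
                vals[a, b] = linear_cka(teacher_reps[ti], student_reps[sj])
            except DegenerateDataError as exc:
                raise DegenerateDataError(
                    f"degenerate representation at teacher layer {ti} / student layer {sj}: {exc}"
                ) from exc
    return CkaMatrix(
        values=vals,
        teacher_layers=t_stage,
        student_layers=s_stage,
        stage=stage,
        batch_size=n,
    )


def save_cka_matrix(cka: CkaMatrix, csv_path, heatmap_path=None) -> None:
    """CSV with layer-id headers; optional heatmap PNG."""
    import pandas as pd

    df = pd.DataFrame(
        cka.values,
        index=[f"teacher_{i}" for i in cka.teacher_layers],
        columns=[f"student_{j}" for j in cka.student_layers],
    )
    Path(csv_path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(csv_path)
    if heatmap_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 3.2))
        im = ax.imshow(cka.values, vmin=0, vmax=1, cmap="magma")
        ax.set_xticks(range(len(cka.student_layers)), [str(j) for j in cka.student_layers])
        ax.set_yticks(range(len(cka.teacher_layers)), [str(i) for i in cka.teacher_layers])
        ax.set_xlabel("student layer")
        ax.set_ylabel("teacher layer")
        ax.set_title(f"CKA ({cka.stage})")
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        fig.savefig(heatmap_path, dpi=110)
        plt.close(fig)
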