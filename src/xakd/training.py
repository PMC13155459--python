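"""Warm-up -> one-shot layer matching -> joint distillation.

Protocol: both models first train with plain cross-entropy (warm-up). The
CKA/KCCA layer matching is then computed once on a fixed probing batch drawn
from the training split and frozen. During distillation the teacher keeps
training on its own cross-entropy while the student minimizes the composite
objective (CE + response KD + stage-wise token/projector alignment +
projector reconstruction); teacher activations and logits enter the student
objective as constants.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix, precision_score, recall_score

from . import nn
from .bridges import (
    AeProjector,
    DistillationTokenBank,
    ae_forward,
    augment_student_tokens,
    cosine_feature_loss,
    extract_token_states,
    recon_loss,
    stage_feature_loss,
)
from .errors import ConfigError, NumericalError
from .fixtures import (
    ModelSpec,
    SyntheticDatasetSpec,
    augment_batch,
    build_tiny_teacher,
    build_tiny_vit_student,
    load_image_folder,
    make_synthetic_dataset,
)
from .kcca import KccaConfig
from .losses import LossWeights, response_kd_loss, total_loss
from .matching import MatchResult, match_layers, save_bridge_map
from .nn import functional as F
from .probes import capture_representations, partition_stages
from .similarity import save_cka_matrix

__all__ = [
    "RunConfig",
    "EvalReport",
    "run_warmup",
    "run_matching",
    "run_distillation",
    "train_ce",
    "evaluate",
    "run_pipeline",
    "build_models",
    "load_dataset",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    dataset: SyntheticDatasetSpec | str = field(default_factory=SyntheticDatasetSpec)
    teacher: ModelSpec = field(
        default_factory=lambda: ModelSpec(role="teacher", family="convolutional", width=16)
    )
    student: ModelSpec = field(
        default_factory=lambda: ModelSpec(role="student", family="transformer", width=32)
    )
    warmup_epochs: int = 3
    distill_epochs: int = 10
    lr: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 1e-3
    step_size: int = 5
    step_gamma: float = 0.1
    batch_size: int = 16
    probe_batch_size: int = 240
    top_k: int = 3
    kcca: KccaConfig = field(default_factory=KccaConfig)
    loss_weights: LossWeights = field(default_factory=LossWeights)
    augment: bool = False  # mild rotation/flip/jitter/blur on training batches
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        for name in ("warmup_epochs", "distill_epochs"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.batch_size < 1 or self.probe_batch_size < 4:
            raise ConfigError("batch sizes invalid (probing batch must be >= 4)")
        if self.lr <= 0:
            raise ConfigError("learning rate must be positive")


@dataclass
class EvalReport:
    split: str
    accuracy: float
    macro_precision: float
    macro_recall: float
    confusion: np.ndarray
    n: int

    def to_dict(self) -> dict:
        return {
            "split": self.split,
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "confusion": self.confusion.tolist(),
            "n": self.n,
        }


def load_dataset(config: RunConfig):
    if isinstance(config.dataset, (str, Path)):
        return load_image_folder(config.dataset)
    return make_synthetic_dataset(config.dataset)


def build_models(config: RunConfig):
    from .models import TinyConvNet, TinyViT

    teacher = TinyConvNet(config.teacher, seed=config.seed + 1)
    student = TinyViT(config.student, seed=config.seed + 2)
    return teacher, student


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def _check_finite(value: float, what: str):
    if not np.isfinite(value):
        raise NumericalError(f"{what} diverged (non-finite loss)")


def predict(model, images, batch_size: int = 64) -> np.ndarray:
    out = []
    with nn.no_grad():
        for start in range(0, len(images), batch_size):
            logits = model.forward(images[start : start + batch_size])
            out.append(np.argmax(np.asarray(logits), axis=1))
    return np.concatenate(out)


def evaluate(model, images, labels, split: str = "test") -> EvalReport:
    """Accuracy plus macro-averaged precision/recall and confusion counts."""
    pred = predict(model, images)
    labels = np.asarray(labels)
    cm = confusion_matrix(labels, pred, labels=np.arange(model.spec.n_classes))
    return EvalReport(
        split=split,
        accuracy=float(np.trace(cm) / cm.sum()),
        macro_precision=float(precision_score(labels, pred, average="macro", zero_division=0)),
        macro_recall=float(recall_score(labels, pred, average="macro", zero_division=0)),
        confusion=cm,
        n=int(cm.sum()),
    )


def train_ce(model, images, labels, epochs: int, config: RunConfig, rng: np.random.Generator):
    """Plain supervised training (cross-entropy, SGD + step schedule)."""
    opt = nn.SGD(model.parameters(), lr=config.lr, momentum=config.momentum,
                 weight_decay=config.weight_decay)
    sched = nn.StepLR(opt, config.step_size, config.step_gamma)
    for _ in range(epochs):
        for idx in _batches(len(images), config.batch_size, rng):
            batch = augment_batch(images[idx], rng) if config.augment else images[idx]
            opt.zero_grad()
            loss = F.cross_entropy(model.forward(batch), labels[idx])
            _check_finite(loss.item(), "CE training")
            loss.backward()
            opt.step()
        sched.step()
    return model


def run_warmup(config: RunConfig, teacher, student, images, labels, splits):
    """CE-only warm-up of both models on the training split."""
    tr = splits["train"]
    rng_t = np.random.default_rng(config.seed + 10)
    rng_s = np.random.default_rng(config.seed + 11)
    if config.warmup_epochs > 0:
        train_ce(teacher, images[tr], labels[tr], config.warmup_epochs, config, rng_t)
        train_ce(student, images[tr], labels[tr], config.warmup_epochs, config, rng_s)
    return teacher, student


def select_probe_batch(config: RunConfig, splits) -> np.ndarray:
    """A fixed probing batch: min(probe_batch_size, train size), dedicated seed."""
    tr = np.asarray(splits["train"])
    rng = np.random.default_rng(config.seed + 20)
    size = min(config.probe_batch_size, len(tr))
    return np.sort(rng.choice(tr, size=size, replace=False))


def run_matching(config: RunConfig, teacher, student, images, splits,
                 out_dir: Path | None = None) -> MatchResult:
    """Probe a fixed batch, compute CKA candidates + KCCA refinement once."""
    probe_idx = select_probe_batch(config, splits)
    batch = images[probe_idx]
    t_reps = capture_representations(teacher, batch)
    s_reps = capture_representations(student, batch)
    t_part = partition_stages(len(t_reps))
    s_part = partition_stages(len(s_reps))
    result = match_layers(t_reps, s_reps, t_part, s_part, k=config.top_k, cfg=config.kcca)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_bridge_map(result.bridges, out_dir / "bridge_map.json")
        for cka in result.cka_matrices:
            save_cka_matrix(cka, out_dir / f"cka_{cka.stage}.csv",
                            out_dir / f"cka_{cka.stage}.png")
        audit = [
            {"stage": cands.stage, "teacher_layer": t, "student_layer": s,
             "cka": score, "rho_bar": scores.get((t, s))}
            for cands, scores in zip(result.candidate_sets, result.kcca_scores)
            for (t, s, score) in cands
        ]
        (out_dir / "candidates.json").write_text(json.dumps(audit, indent=2))
    return result


def run_distillation(config: RunConfig, teacher, student, match: MatchResult,
                     images, labels, splits, out_dir: Path | None = None):
    """Joint distillation per the composite objective; returns
    (augmented student, final EvalReport on the test split)."""
    bridges = match.bridges if isinstance(match, MatchResult) else list(match)
    n_t_layers = len(teacher.probe_points)
    n_s_layers = len(student.probe_points)
    for b in bridges:
        if not (0 <= b.teacher_layer < n_t_layers and 0 <= b.student_layer < n_s_layers):
            raise ConfigError(
                f"bridge {b.stage} references layers outside the models: "
                f"teacher {b.teacher_layer}, student {b.student_layer}"
            )

    bank = DistillationTokenBank(
        embed_dim=config.student.width,
        extraction_depths=[b.student_layer for b in bridges],
        n_layers=n_s_layers,
        seed=config.seed + 30,
    )
    aug = augment_student_tokens(student, bank)
    projectors = [
        AeProjector(teacher.channels[b.teacher_layer], latent_dim=config.student.width,
                    seed=config.seed + 40 + i)
        for i, b in enumerate(bridges)
    ]

    t_opt = nn.SGD(teacher.parameters(), lr=config.lr, momentum=config.momentum,
                   weight_decay=config.weight_decay)
    s_params = student.parameters() + bank.parameters()
    for proj in projectors:
        s_params += proj.parameters()
    s_opt = nn.SGD(s_params, lr=config.lr, momentum=config.momentum,
                   weight_decay=config.weight_decay)
    t_sched = nn.StepLR(t_opt, config.step_size, config.step_gamma)
    s_sched = nn.StepLR(s_opt, config.step_size, config.step_gamma)

    tr = splits["train"]
    rng = np.random.default_rng(config.seed + 50)
    w = config.loss_weights
    log_rows = []
    for epoch in range(config.distill_epochs):
        for step, idx in enumerate(_batches(len(tr), config.batch_size, rng)):
            x, y = images[tr[idx]], labels[tr[idx]]
            if config.augment:
                x = augment_batch(x, rng)
            # teacher keeps fine-tuning on its own CE
            t_opt.zero_grad()
            t_logits, t_feats = teacher.forward_features(x)
            t_loss = F.cross_entropy(t_logits, y)
            _check_finite(t_loss.item(), "teacher CE")
            t_loss.backward()
            t_opt.step()

            # student composite objective (teacher outputs as constants)
            s_opt.zero_grad()
            s_logits, s_feats = aug.forward_features(x)
            token_states = extract_token_states(aug, feats=s_feats)
            stage_losses, recon_losses = [], []
            for proj, bridge, token in zip(projectors, bridges, token_states):
                v, f, f_hat = ae_forward(proj, t_feats[f"stage{bridge.teacher_layer}"])
                stage_losses.append(cosine_feature_loss(v, token))
                recon_losses.append(recon_loss(f, f_hat))
            l_feat = stage_feature_loss(stage_losses, w.stage_weights)
            l_recon = sum(recon_losses[1:], recon_losses[0]) * (1.0 / len(recon_losses))
            l_cls = F.cross_entropy(s_logits, y)
            l_kd = response_kd_loss(np.asarray(t_logits), s_logits, w.temperature)
            total, breakdown = total_loss(l_cls, l_kd, l_feat, l_recon, w)
            _check_finite(breakdown.l_total, "distillation")
            total.backward()
            s_opt.step()
            log_rows.append(
                [epoch, step, breakdown.l_cls, breakdown.l_kd]
                + [float(sl) for sl in stage_losses]
                + [breakdown.l_recon, breakdown.l_total]
            )
        t_sched.step()
        s_sched.step()

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "loss_log.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["epoch", "step", "l_cls", "l_kd",
                 "l_feat_early", "l_feat_mid", "l_feat_late", "l_recon", "l_total"]
            )
            writer.writerows(log_rows)
    report = evaluate(aug, images[splits["test"]], labels[splits["test"]], split="test")
    return aug, report


def _file_sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Full run: data -> warm-up -> one-shot matching -> distillation -> eval.

    Writes bridge map, audit CSVs, loss log, metrics JSON and an attention
    overlay PNG when `config.out_dir` is set. Returns a results dict.
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    images, labels, splits = load_dataset(config)
    teacher, student = build_models(config)
    run_warmup(config, teacher, student, images, labels, splits)
    warm_teacher = evaluate(teacher, images[splits["test"]], labels[splits["test"]])
    match = run_matching(config, teacher, student, images, splits, out_dir)
    bridge_hash = _file_sha256(out_dir / "bridge_map.json") if out_dir else None
    aug, report = run_distillation(
        config, teacher, student, match, images, labels, splits, out_dir
    )
    results = {
        "teacher_post_warmup": warm_teacher.to_dict(),
        "student_test": report.to_dict(),
        "bridges": {b.stage: b.to_dict() for b in match.bridges},
    }
    if out_dir is not None:
        assert bridge_hash == _file_sha256(out_dir / "bridge_map.json"), \
            "bridge map changed during distillation"
        results["bridge_map_sha256"] = bridge_hash
        (out_dir / "metrics.json").write_text(json.dumps(results, indent=2))
        _save_attention_overlay(aug, images[splits["test"]][0], out_dir / "attention.png")
        (out_dir / "manifest.json").write_text(json.dumps(
            {"files": sorted(p.name for p in out_dir.iterdir())}, indent=2))
    return results


def _save_attention_overlay(model, image, path) -> None:
    from .probes import extract_attention_map

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    amap = extract_attention_map(model, image)
    fig, ax = plt.subplots(figsize=(3, 3))
    ax.imshow(image)
    ax.imshow(amap.overlay, cmap="jet", alpha=0.45)
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
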