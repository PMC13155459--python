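"""Orchestration: warm-up, probing batch, evaluation, and the smoke pipeline."""

import json

import numpy as np
import pytest

from xakd.errors import ConfigError
from xakd.fixtures import ModelSpec, SyntheticDatasetSpec
from xakd.losses import LossWeights
from xakd.matching import BridgePair
from xakd.training import (
    EvalReport,
    RunConfig,
    build_models,
    evaluate,
    load_dataset,
    run_distillation,
    run_matching,
    run_pipeline,
    run_warmup,
    select_probe_batch,
    train_ce,
)


@pytest.fixture(scope="module")
def smoke_config(tmp_path_factory):
    return RunConfig(
        dataset=SyntheticDatasetSpec(n_classes=8, n_per_class=8, image_size=32, seed=21),
        teacher=ModelSpec(role="teacher", family="convolutional", depth=4, width=8,
                          n_classes=8, image_size=32),
        student=ModelSpec(role="student", family="transformer", depth=4, width=32,
                          patch_size=8, n_heads=4, n_classes=8, image_size=32),
        warmup_epochs=1,
        distill_epochs=1,
        probe_batch_size=24,
        seed=5,
        out_dir=str(tmp_path_factory.mktemp("smoke_run")),
    )


class TestEvaluate:
    def test_perfect_and_constant_predictors(self, small_dataset, tiny_student):
        images, labels, splits = small_dataset
        te = splits["test"]

        class Oracle:
            spec = tiny_student.spec

            def forward(self, x):
                idx = [np.flatnonzero((images == im).all(axis=(1, 2, 3)))[0] for im in x]
                return np.eye(8)[labels[idx]]

        class Constant:
            spec = tiny_student.spec

            def forward(self, x):
                out = np.zeros((len(x), 8))
                out[:, 2] = 1.0
                return out

        perfect = evaluate(Oracle(), images[te], labels[te])
        assert perfect.accuracy == 1.0
        assert perfect.macro_precision == 1.0
        const = evaluate(Constant(), images[te], labels[te])
        assert const.accuracy == pytest.approx(1 / 8)
        assert const.confusion.sum() == len(te) == const.n

    def test_confusion_trace_is_accuracy(self, small_dataset, tiny_student):
        images, labels, splits = small_dataset
        report = evaluate(tiny_student, images[splits["val"]], labels[splits["val"]])
        assert report.accuracy == pytest.approx(
            np.trace(report.confusion) / report.confusion.sum())


class TestWarmup:
    def test_zero_epochs_leaves_models_untouched(self, smoke_config, small_dataset):
        import dataclasses

        cfg = dataclasses.replace(smoke_config, warmup_epochs=0)
        images, labels, splits = load_dataset(cfg)
        teacher, student = build_models(cfg)
        before_t = [p.data.copy() for p in teacher.parameters()]
        before_s = [p.data.copy() for p in student.parameters()]
        run_warmup(cfg, teacher, student, images, labels, splits)
        assert all(np.array_equal(a, p.data)
                   for a, p in zip(before_t, teacher.parameters()))
        assert all(np.array_equal(a, p.data)
                   for a, p in zip(before_s, student.parameters()))

    def test_warmup_is_seed_deterministic(self, smoke_config):
        images, labels, splits = load_dataset(smoke_config)
        accs = []
        for _ in range(2):
            teacher, student = build_models(smoke_config)
            run_warmup(smoke_config, teacher, student, images, labels, splits)
            accs.append(evaluate(teacher, images[splits["test"]],
                                 labels[splits["test"]]).accuracy)
        assert accs[0] == accs[1]

    def test_teacher_beats_binomial_chance_after_five_epochs(self):
        cfg = RunConfig(
            dataset=SyntheticDatasetSpec(n_classes=8, n_per_class=30, image_size=32, seed=2),
            teacher=ModelSpec(role="teacher", family="convolutional", depth=4, width=8,
                              n_classes=8, image_size=32),
            seed=3,
        )
        images, labels, splits = load_dataset(cfg)
        teacher, _ = build_models(cfg)
        tr, te = splits["train"], splits["test"]
        train_ce(teacher, images[tr], labels[tr], 5, cfg, np.random.default_rng(4))
        acc = evaluate(teacher, images[te], labels[te]).accuracy
        p0 = 1 / 8
        threshold = p0 + 3 * np.sqrt(p0 * (1 - p0) / len(te))
        assert acc > threshold


class TestProbeBatch:
    def test_size_and_train_membership(self, smoke_config):
        _, _, splits = load_dataset(smoke_config)
        idx = select_probe_batch(smoke_config, splits)
        assert len(idx) == min(smoke_config.probe_batch_size, len(splits["train"]))
        assert np.all(np.isin(idx, splits["train"]))
        assert np.array_equal(idx, select_probe_batch(smoke_config, splits))

    def test_default_probing_batch_is_240(self):
        assert RunConfig().probe_batch_size == 240


class TestPipeline:
    def test_smoke_run_artifacts_and_schema(self, smoke_config):
        results = run_pipeline(smoke_config)
        out = smoke_config.out_dir
        from pathlib import Path

        out = Path(out)
        for fname in ("bridge_map.json", "metrics.json", "loss_log.csv",
                      "candidates.json", "attention.png", "manifest.json",
                      "cka_early.csv", "cka_mid.csv", "cka_late.csv"):
            assert (out / fname).exists(), fname
        report = results["student_test"]
        assert set(report) >= {"accuracy", "macro_precision", "macro_recall",
                               "confusion", "n"}
        assert 0.0 <= report["accuracy"] <= 1.0
        assert set(results["bridges"]) == {"early", "mid", "late"}
        # loss log exposes exactly the three per-stage feature columns
        header = (out / "loss_log.csv").read_text().splitlines()[0].split(",")
        assert [c for c in header if c.startswith("l_feat_")] == [
            "l_feat_early", "l_feat_mid", "l_feat_late"]
        # bridge map on disk matches the returned bridges (frozen contract)
        on_disk = json.loads((out / "bridge_map.json").read_text())
        assert on_disk == results["bridges"]

    def test_out_of_range_bridge_rejected_before_training(self, smoke_config):
        images, labels, splits = load_dataset(smoke_config)
        teacher, student = build_models(smoke_config)
        bad = [BridgePair("early", 0, 9, 0.5, 0.5),
               BridgePair("mid", 1, 1, 0.5, 0.5),
               BridgePair("late", 2, 2, 0.5, 0.5)]
        with pytest.raises(ConfigError):
            run_distillation(smoke_config, teacher, student, bad, images, labels, splits)

    def test_gamma_zero_alpha_one_reduces_to_cross_entropy(self, smoke_config, rng):
        # composition contract: the composite objective with alpha=1, gamma=0
        # equals plain CE on the same logits
        from xakd.losses import total_loss
        from xakd.nn import functional as F

        images, labels, splits = load_dataset(smoke_config)
        _, student = build_models(smoke_config)
        batch = splits["train"][:8]
        logits = student.forward(images[batch])
        ce = F.cross_entropy(logits, labels[batch])
        total, _ = total_loss(ce, 5.0, 7.0, 3.0, LossWeights(alpha=1.0, gamma=0.0))
        assert float(total) == pytest.approx(ce.item())
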