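"""Distillation tokens, AE projectors, and the feature-distillation losses."""

import numpy as np
import pytest

from xakd import nn
from xakd.bridges import (
    AeProjector,
    DistillationTokenBank,
    ae_forward,
    augment_student_tokens,
    cosine_feature_loss,
    extract_token_states,
    recon_loss,
    stage_feature_loss,
)
from xakd.errors import ConfigError, DegenerateDataError, ValidationError


@pytest.fixture
def bank():
    return DistillationTokenBank(embed_dim=32, extraction_depths=[0, 1, 3], n_layers=4, seed=3)


class TestTokenAugmentation:
    def test_sequence_grows_by_three(self, tiny_student, bank, probe_batch):
        aug = augment_student_tokens(tiny_student, bank)
        assert aug.seq_len == 17 + 3 == 20
        _, feats = aug.forward_features(probe_batch[:4])
        assert feats["block0"].shape == (4, 20, 32)

    def test_reaugmentation_rejected(self, tiny_student, bank):
        aug = augment_student_tokens(tiny_student, bank)
        with pytest.raises(ConfigError):
            augment_student_tokens(aug, bank)

    def test_extraction_depths_validate_against_model(self):
        with pytest.raises(ConfigError):
            DistillationTokenBank(32, [0, 1, 7], n_layers=4)
        with pytest.raises(ConfigError):
            DistillationTokenBank(32, [0, 1], n_layers=4)

    def test_extraction_is_read_only_on_logits(self, tiny_student, bank, probe_batch):
        aug = augment_student_tokens(tiny_student, bank)
        batch = probe_batch[:5]
        logits_plain = np.asarray(aug.forward(batch))
        logits2, feats = aug.forward_features(batch)
        states = extract_token_states(aug, feats=feats)
        assert len(states) == 3
        assert all(s.shape == (5, 32) for s in states)
        np.testing.assert_array_equal(logits_plain, np.asarray(logits2))

    def test_last_block_state_equals_final_sequence_slot(self, tiny_student, bank, probe_batch):
        aug = augment_student_tokens(tiny_student, bank)
        _, feats = aug.forward_features(probe_batch[:4])
        states = extract_token_states(aug, feats=feats)
        # stage 2 extracts at depth 3 (the last block), token slot 17 + 2
        np.testing.assert_array_equal(
            np.asarray(states[2]), np.asarray(feats["block3"])[:, 19, :])

    def test_classifier_head_reads_cls_only(self, tiny_student, bank, probe_batch):
        aug = augment_student_tokens(tiny_student, bank)
        batch = probe_batch[:4]
        _, feats = aug.forward_features(batch)
        final = feats["block3"]
        cls_state = tiny_student.norm(final[:, 0, :])
        np.testing.assert_allclose(
            np.asarray(tiny_student.head(cls_state)), np.asarray(aug.forward(batch)),
            atol=1e-12)


class TestAeProjector:
    def test_dimension_contract(self, rng):
        proj = AeProjector(in_channels=16, latent_dim=192, seed=0)
        F = rng.normal(size=(6, 16, 7, 7))
        v, f, f_hat = ae_forward(proj, F)
        assert v.shape == (6, 192)
        assert f.shape == (6, 16)
        assert f_hat.shape == (6, 16)
        assert proj.enc1.weight.shape == (16, 512)  # hidden width 512

    def test_pooled_vector_is_gap(self):
        proj = AeProjector(in_channels=3, latent_dim=8, seed=0)
        F = np.full((2, 3, 4, 4), 1.5)
        _, f, _ = ae_forward(proj, F)
        np.testing.assert_allclose(np.asarray(f), 1.5)

    def test_channel_mismatch_rejected(self, rng):
        proj = AeProjector(in_channels=16, latent_dim=8, seed=0)
        with pytest.raises(ValidationError):
            ae_forward(proj, rng.normal(size=(4, 8, 5, 5)))

    def test_teacher_features_enter_as_constants(self, rng):
        # gradient isolation: the pooled teacher vector carries no graph
        proj = AeProjector(in_channels=4, latent_dim=6, seed=0)
        src = nn.Parameter(rng.normal(size=(3, 4, 5, 5)))
        feature = src * 2.0  # a graph tensor, as during training
        v, f, f_hat = ae_forward(proj, feature)
        loss = recon_loss(f, f_hat) + cosine_feature_loss(v, rng.normal(size=(3, 6)))
        loss.backward()
        assert src.grad is None
        assert proj.enc1.weight.grad is not None

    def test_reconstruction_improves_under_training(self, rng):
        proj = AeProjector(in_channels=12, latent_dim=8, seed=1)
        F = rng.normal(size=(16, 12, 4, 4))
        opt = nn.SGD(proj.parameters(), lr=0.05, momentum=0.9)
        losses = []
        for _ in range(50):
            opt.zero_grad()
            _, f, f_hat = ae_forward(proj, F)
            loss = recon_loss(f, f_hat)
            losses.append(loss.item())
            loss.backward()
            opt.step()
        assert losses[-1] < losses[0]
        assert losses[-1] < 0.5 * losses[0]  # strict, substantial decrease


class TestFeatureLosses:
    def test_cosine_loss_identity_orthogonal_scale(self, rng):
        v = rng.normal(size=12)
        assert cosine_feature_loss(v, v).item() == pytest.approx(0.0, abs=1e-12)
        a, b = np.zeros(4), np.zeros(4)
        a[0], b[1] = 1.0, 1.0
        assert cosine_feature_loss(a, b).item() == pytest.approx(1.0)
        t = rng.normal(size=12)
        assert cosine_feature_loss(v, 7.3 * t).item() == pytest.approx(
            cosine_feature_loss(v, t).item(), abs=1e-10)
        assert 0.0 <= cosine_feature_loss(v, -v).item() <= 2.0 + 1e-12

    def test_cosine_loss_zero_norm_rejected(self):
        with pytest.raises(DegenerateDataError):
            cosine_feature_loss(np.zeros(4), np.ones(4))

    def test_recon_loss_examples_and_loop_oracle(self, rng):
        f = rng.normal(size=(5, 7))
        assert recon_loss(f, f).item() == pytest.approx(0.0)
        assert recon_loss(f, f + 1.0).item() == pytest.approx(1.0)
        g = rng.normal(size=(5, 7))
        oracle = sum(
            (f[i, j] - g[i, j]) ** 2 for i in range(5) for j in range(7)
        ) / 35
        assert recon_loss(f, g).item() == pytest.approx(oracle)

    def test_stage_weighting_presets(self):
        losses = (2.0, 3.0, 5.0)
        assert stage_feature_loss(losses, (1, 1, 0)) == pytest.approx(5.0)
        assert stage_feature_loss(losses, (0, 1, 1)) == pytest.approx(8.0)
        assert stage_feature_loss(losses, (1, 1, 1)) == pytest.approx(10.0)
        assert stage_feature_loss(losses, (0, 0, 0)) == pytest.approx(0.0)

    def test_primary_preset_is_early_mid(self):
        from xakd.losses import STAGE_WEIGHT_PRESETS, LossWeights

        assert LossWeights().stage_weights == (1, 1, 0)
        assert STAGE_WEIGHT_PRESETS["early_mid"] == (1, 1, 0)
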