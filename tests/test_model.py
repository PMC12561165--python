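import numpy as np
import pytest

from rtcn.model import (RTCN, Bottleneck, RtcnConfig, STAGE_PLAN,
                        TokenCompressor, build_backbone, backbone_out_channels,
                        count_weight_layers)

SCALED = dict(input_side=64, width_divisor=8, compressed_dim=32, n_heads=4,
              n_encoder_layers=1, dropout=0.0)


@pytest.fixture(scope="module")
def scaled_model():
    m = RTCN(RtcnConfig(**SCALED, seed=0))
    m.eval()
    return m


class TestBackboneStructure:
    def test_stage_plan_matches_resnet50(self):
        assert [blocks for _, blocks, _ in STAGE_PLAN] == [3, 4, 6, 3]
        assert [mid for mid, _, _ in STAGE_PLAN] == [64, 128, 256, 512]

    def test_weight_layer_count_is_fifty(self):
        assert count_weight_layers(RtcnConfig()) == 50

    def test_scaled_backbone_output_grid(self, scaled_model):
        x = np.random.default_rng(0).random((1, 3, 64, 64))
        feat = scaled_model.backbone(x)
        assert feat.shape == (1, backbone_out_channels(scaled_model.config), 2, 2)

    def test_bottleneck_kernel_sizes_and_widths(self):
        rng = np.random.default_rng(0)
        blk = Bottleneck(64, 64, 256, 1, rng)
        assert blk.conv1.weight.shape == (64, 64, 1, 1)
        assert blk.conv2.weight.shape == (64, 64, 3, 3)
        assert blk.conv3.weight.shape == (256, 64, 1, 1)

    def test_zero_input_forward_is_finite(self, scaled_model):
        out = scaled_model(np.zeros((1, 3, 64, 64)))
        assert np.all(np.isfinite(out))

    def test_wrong_input_shape_rejected(self, scaled_model):
        with pytest.raises(ValueError, match="expected input"):
            scaled_model(np.zeros((1, 3, 32, 32)))


class TestTokenizer:
    def _tokenizer_and_config(self, d=16):
        cfg = RtcnConfig(input_side=224, compressed_dim=d, n_heads=4, dropout=0.0)
        rng = np.random.default_rng(0)
        return TokenCompressor(8, cfg, rng), cfg

    def test_sequence_length_and_dim(self):
        tok, cfg = self._tokenizer_and_config()
        out = tok(np.random.default_rng(1).random((2, 8, 7, 7)))
        assert out.shape == (2, cfg.n_tokens + 1, cfg.compressed_dim)
        assert cfg.n_tokens == 49

    def test_constant_featmap_gives_identical_tokens(self):
        tok, _ = self._tokenizer_and_config()
        tok.pos_embed.value[...] = 0.0
        out = tok(np.ones((1, 8, 7, 7)))
        spatial = out[0, 1:, :]
        assert np.max(np.abs(spatial - spatial[0])) < 1e-12

    def test_spatial_permutation_equivariance_before_positions(self):
        tok, _ = self._tokenizer_and_config()
        tok.pos_embed.value[...] = 0.0
        rng = np.random.default_rng(2)
        feat = rng.random((1, 8, 7, 7))
        perm = rng.permutation(49)
        feat_p = feat.reshape(1, 8, 49)[:, :, perm].reshape(1, 8, 7, 7)
        t1 = tok(feat)[0, 1:, :]
        t2 = tok(feat_p)[0, 1:, :]
        np.testing.assert_allclose(t1[perm], t2, atol=1e-12)


class TestEncoderAndHead:
    def test_attention_rows_sum_to_one_and_shape_preserved(self, scaled_model):
        x = np.random.default_rng(3).random((2, 3, 64, 64))
        scaled_model(x)
        for layer in scaled_model.encoder:
            att = layer.attn.last_attention
            np.testing.assert_allclose(att.sum(axis=-1), 1.0, atol=1e-6)

    def test_residual_pass_through_when_heads_and_ffn_zeroed(self):
        from rtcn import nn
        rng = np.random.default_rng(0)
        layer = nn.TransformerEncoderLayer(8, 2, 16, 0.0, rng)
        layer.attn.wo.weight.value[...] = 0.0
        layer.attn.wo.bias.value[...] = 0.0
        layer.ff2.weight.value[...] = 0.0
        layer.ff2.bias.value[...] = 0.0
        x = rng.standard_normal((1, 2, 8))
        ln = nn.LayerNorm(8)
        np.testing.assert_allclose(layer(x), ln(ln(x)), atol=1e-9)

    def test_classify_simplex_uniform_and_shift_invariance(self, scaled_model):
        rng = np.random.default_rng(4)
        enc = rng.standard_normal((3, 5, scaled_model.config.compressed_dim))
        p = scaled_model.classify(enc)
        assert p.shape == (3, 12)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        # zero head -> uniform
        w_save = scaled_model.head.weight.value.copy()
        b_save = scaled_model.head.bias.value.copy()
        scaled_model.head.weight.value[...] = 0.0
        scaled_model.head.bias.value[...] = 0.0
        np.testing.assert_allclose(scaled_model.classify(enc), 1 / 12, atol=1e-12)
        scaled_model.head.weight.value[...] = w_save
        # adding a constant to every logit leaves probabilities unchanged
        scaled_model.head.bias.value[...] = 3.14
        np.testing.assert_allclose(scaled_model.classify(enc), p, atol=1e-9)
        scaled_model.head.bias.value[...] = b_save


class TestForward:
    def test_inference_determinism(self, scaled_model):
        x = np.random.default_rng(5).random((1, 3, 64, 64))
        np.testing.assert_array_equal(scaled_model.predict_proba(x),
                                      scaled_model.predict_proba(x))

    def test_batch_equals_concatenated_singles(self, scaled_model):
        x = np.random.default_rng(6).random((2, 3, 64, 64))
        batch = scaled_model.predict_proba(x)
        singles = np.vstack([scaled_model.predict_proba(x[:1]),
                             scaled_model.predict_proba(x[1:])])
        np.testing.assert_allclose(batch, singles, atol=1e-6)

    def test_ablation_variants_constructible_from_same_config_surface(self):
        for variant in ("resnet", "vit"):
            m = RTCN(RtcnConfig(**{**SCALED, "compressed_dim": 32},
                                variant=variant, vit_patch=16, seed=0))
            m.eval()
            p = m.predict_proba(np.random.default_rng(7).random((1, 3, 64, 64)))
            np.testing.assert_allclose(p.sum(), 1.0, atol=1e-6)

    def test_dropout_only_in_training_mode(self):
        m = RTCN(RtcnConfig(**{**SCALED, "dropout": 0.0}, seed=0))
        m.config.dropout = 0.5  # rebuild-free check via tokenizer dropout
        m.tokenizer.drop.p = 0.5
        x = np.random.default_rng(8).random((1, 3, 64, 64))
        m.eval()
        np.testing.assert_array_equal(m.predict_proba(x), m.predict_proba(x))
        m.train()
        a = m(x)
        b = m(x)
        assert np.max(np.abs(a - b)) > 0  # stochastic in training mode

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            RtcnConfig(compressed_dim=30, n_heads=4)
        with pytest.raises(ValueError):
            RtcnConfig(input_side=100)
        with pytest.raises(ValueError):
            RtcnConfig(variant="mlp")
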