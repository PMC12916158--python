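"""Architecture variants: shapes, contracts, checkpointing, gradient flow."""

import numpy as np
import pytest

from eegmtl import (
    ConfigError,
    ModelConfig,
    VariantInterfaceError,
    VariantSpec,
    build_model,
    count_parameters,
    load_checkpoint,
    save_checkpoint,
)
from eegmtl.network import VARIANTS
from eegmtl.training import cross_entropy


@pytest.fixture
def batch(rng):
    return rng.normal(size=(8, 4, 200)).astype(np.float32)


class TestModelConfig:
    def test_width_head_divisibility_enforced(self):
        with pytest.raises(ConfigError):
            ModelConfig(d_model=30, n_heads=4, conv_channels=(16, 30))

    def test_conv_output_must_match_model_width(self):
        with pytest.raises(ConfigError):
            ModelConfig(d_model=64, conv_channels=(32, 48))

    def test_unknown_variant_rejected(self):
        with pytest.raises(ConfigError):
            VariantSpec("resnet")


class TestConvEncoder:
    def test_output_length_halves_twice(self, small_model_config, rng):
        """kernel 5, stride 2, padding 2: 1000 -> 500 -> 250."""
        m = build_model(small_model_config, "full", seed=0)
        x = rng.normal(size=(2, 4, 1000)).astype(np.float32)
        z = m.conv_encode(x)
        assert z.shape == (2, 250, small_model_config.d_model)

    def test_short_input_rejected(self, small_model_config):
        m = build_model(small_model_config, "full", seed=0)
        with pytest.raises(ValueError):
            m.conv_encode(np.zeros((1, 4, 0), dtype=np.float32))

    def test_zero_input_gives_nonnegative_relu_output(self, small_model_config):
        m = build_model(small_model_config, "full", seed=0).eval()
        z = m.conv_encode(np.zeros((2, 4, 64), dtype=np.float32))
        assert (z >= 0).all() and np.isfinite(z).all()


class TestClsAndTransformer:
    def test_cls_prepend_extends_sequence(self, small_model_config, rng):
        m = build_model(small_model_config, "full", seed=0)
        z = rng.normal(size=(3, 250, 16)).astype(np.float32)
        out = m.prepend_cls(z)
        assert out.shape == (3, 251, 16)

    def test_cls_row_shared_across_batch(self, small_model_config, rng):
        m = build_model(small_model_config, "full", seed=0)
        z = rng.normal(size=(4, 10, 16)).astype(np.float32)
        out = m.prepend_cls(z)
        for i in range(1, 4):
            np.testing.assert_array_equal(out[0, 0], out[i, 0])

    def test_without_positional_rows_pass_through(self, rng):
        cfg = ModelConfig(
            conv_channels=(8, 16), d_model=16, n_heads=2, ffn_dim=32,
            head_hidden=8, n_subjects=3, use_positional=False, max_seq_len=64,
        )
        m = build_model(cfg, "full", seed=0)
        z = rng.normal(size=(2, 10, 16)).astype(np.float32)
        out = m.prepend_cls(z)
        np.testing.assert_array_equal(out[:, 1:, :], z)

    def test_permutation_invariance_without_positional(self, rng):
        cfg = ModelConfig(
            conv_channels=(8, 16), d_model=16, n_heads=2, ffn_dim=32,
            head_hidden=8, n_subjects=3, dropout=0.0, use_positional=False,
            max_seq_len=64,
        )
        m = build_model(cfg, "full", seed=0).eval()
        z = rng.normal(size=(2, 12, 16)).astype(np.float32)
        h1 = m.transformer_encode(m.prepend_cls(z))
        perm = rng.permutation(12)
        h2 = m.transformer_encode(m.prepend_cls(z[:, perm, :]))
        np.testing.assert_allclose(h1, h2, atol=1e-5)

    def test_zero_layers_returns_cls_row(self, rng):
        cfg = ModelConfig(
            conv_channels=(8, 16), d_model=16, n_layers=0, n_heads=2,
            ffn_dim=32, head_hidden=8, n_subjects=3, use_positional=False,
            max_seq_len=64,
        )
        m = build_model(cfg, "full", seed=0).eval()
        z = rng.normal(size=(2, 6, 16)).astype(np.float32)
        h = m.transformer_encode(m.prepend_cls(z))
        np.testing.assert_array_equal(h, np.broadcast_to(m.cls.data, (2, 16)))

    def test_output_width_is_d_model(self, small_model_config, rng):
        m = build_model(small_model_config, "full", seed=0).eval()
        for T in (8, 33):
            z = rng.normal(size=(2, T, 16)).astype(np.float32)
            assert m.transformer_encode(m.prepend_cls(z)).shape == (2, 16)


class TestHeadsAndVariants:
    def test_bio_head_width_matches_subject_count(self, batch):
        cfg = ModelConfig(
            conv_channels=(8, 16), d_model=16, n_heads=2, ffn_dim=32,
            head_hidden=8, n_subjects=20, max_seq_len=64,
        )
        out = build_model(cfg, "full", seed=0).eval().forward(batch)
        assert out.logits_bio.shape == (8, 20)
        assert out.logits_lang.shape == (8, 2)
        assert out.logits_dev.shape == (8, 2)

    def test_probabilities_normalized(self, small_model_config, batch):
        out = build_model(small_model_config, "full", seed=0).eval().forward(batch)
        for t in ("bio", "lang", "dev"):
            p = out.probabilities(t)
            assert (p >= 0).all()
            np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-6)

    def test_single_task_variant_hides_other_heads(self, small_model_config, batch):
        out = build_model(small_model_config, "stt_bio", seed=0).eval().forward(batch)
        assert out.tasks == ("bio",)
        with pytest.raises(VariantInterfaceError):
            out.logits_lang

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_every_variant_forward_is_finite(self, small_model_config, variant, rng):
        x = rng.normal(size=(8, 4, 1000)).astype(np.float32)
        out = build_model(small_model_config, variant, seed=0).eval().forward(x)
        for t in out.tasks:
            logits = out.logits(t)
            assert np.isfinite(logits).all()
            k = small_model_config.n_subjects if t == "bio" else 2
            assert logits.shape == (8, k)

    def test_full_has_more_parameters_than_no_transformer(self, small_model_config):
        full = count_parameters(build_model(small_model_config, "full", seed=0))
        ablated = count_parameters(build_model(small_model_config, "no_transformer", seed=0))
        assert full > ablated

    def test_parameter_count_matches_component_tally(self, small_model_config):
        m = build_model(small_model_config, "full", seed=0)
        tally = sum(p.data.size for _, p in m.named_parameters())
        assert count_parameters(m) == tally
        # linear layer arithmetic: 64 -> 20 with bias
        from eegmtl import nn

        lin = nn.Linear(64, 20, np.random.default_rng(0))
        assert sum(p.size for p in lin.parameters()) == 64 * 20 + 20


class TestTrainingDynamics:
    def test_gradients_reach_every_head_and_trunk(self, small_model_config, batch, rng):
        m = build_model(small_model_config, "full", seed=0)
        m.train()
        y = {
            "bio": rng.integers(0, 3, 8),
            "lang": rng.integers(0, 2, 8),
            "dev": rng.integers(0, 2, 8),
        }
        out = m.forward(batch)
        m.zero_grad()
        grads = {t: cross_entropy(out.logits(t), y[t])[1] for t in out.tasks}
        m.backward(grads)
        for name, p in m.named_parameters():
            assert np.any(p.grad != 0), f"no gradient reached {name}"

    def test_eval_forward_deterministic(self, small_model_config, batch):
        m = build_model(small_model_config, "full", seed=0).eval()
        a = m.forward(batch).logits_bio
        b = m.forward(batch).logits_bio
        np.testing.assert_array_equal(a, b)

    def test_checkpoint_round_trip_bit_exact(self, small_model_config, batch, tmp_path):
        m = build_model(small_model_config, "full", seed=3)
        # push batchnorm stats away from init
        m.train()
        m.forward(batch)
        m.eval()
        want = m.forward(batch).logits_bio
        path = tmp_path / "ckpt.npz"
        save_checkpoint(m, path)
        m2 = load_checkpoint(path)
        got = m2.eval().forward(batch).logits_bio
        np.testing.assert_array_equal(got, want)
        assert m2.variant.variant == "full"
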