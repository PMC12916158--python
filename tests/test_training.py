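"""Loss identities, LR schedule, early stopping and determinism."""

import numpy as np
import pytest

from eegmtl import (
    ConfigError,
    LabelError,
    ModelConfig,
    ParameterError,
    TrainConfig,
    build_model,
    joint_loss,
    lr_at_epoch,
    train,
)
from eegmtl.network import ForwardOutput
from eegmtl.training import cross_entropy, set_global_seed


def _uniform_output(n=6, n_subjects=20):
    logits = {
        "bio": np.zeros((n, n_subjects)),
        "lang": np.zeros((n, 2)),
        "dev": np.zeros((n, 2)),
    }
    return ForwardOutput(logits, np.zeros((n, 4)))


def _labels(n=6, n_subjects=20, seed=0):
    rng = np.random.default_rng(seed)
    return {
        "bio": rng.integers(0, n_subjects, n),
        "lang": rng.integers(0, 2, n),
        "dev": rng.integers(0, 2, n),
    }


class TestJointLoss:
    def test_uniform_prediction_gives_log_class_counts(self):
        lb = joint_loss(_uniform_output(), _labels())
        assert lb.bio == pytest.approx(np.log(20), abs=1e-12)
        assert lb.lang == pytest.approx(np.log(2), abs=1e-12)
        assert lb.dev == pytest.approx(np.log(2), abs=1e-12)
        assert lb.total == pytest.approx(np.log(20) + 2 * np.log(2), abs=1e-12)
        assert lb.total == pytest.approx(4.3820, abs=5e-4)

    def test_perfect_prediction_gives_zero(self):
        y = _labels(n=4)
        logits = {}
        for t, k in (("bio", 20), ("lang", 2), ("dev", 2)):
            l = np.full((4, k), -1e4)
            l[np.arange(4), y[t]] = 1e4
            logits[t] = l
        lb = joint_loss(ForwardOutput(logits, np.zeros((4, 4))), y)
        assert lb.total == pytest.approx(0.0, abs=1e-9)

    def test_weights_select_components(self):
        y = _labels()
        lb = joint_loss(_uniform_output(), y, weights=(1.0, 0.0, 0.0))
        assert lb.total == pytest.approx(lb.bio, abs=1e-12)

    def test_total_is_weighted_sum(self):
        y = _labels(seed=4)
        w = (0.5, 2.0, 1.5)
        lb = joint_loss(_uniform_output(), y, weights=w)
        assert lb.total == pytest.approx(
            w[0] * lb.bio + w[1] * lb.lang + w[2] * lb.dev, abs=1e-9
        )

    def test_hand_computed_three_sample_batch(self):
        """Cross-entropy equals the direct formula on explicit probabilities."""
        logits = np.log(np.array([[0.7, 0.2, 0.1], [0.1, 0.8, 0.1], [0.25, 0.25, 0.5]]))
        y = np.array([0, 1, 2])
        want = -(np.log(0.7) + np.log(0.8) + np.log(0.5)) / 3
        loss, grad = cross_entropy(logits, y)
        assert loss == pytest.approx(want, abs=1e-12)
        # gradient: (p - onehot)/n
        p = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        onehot = np.eye(3)[y]
        np.testing.assert_allclose(grad, (p - onehot) / 3, atol=1e-12)

    def test_out_of_range_label_reported(self):
        with pytest.raises(LabelError, match="7"):
            cross_entropy(np.zeros((3, 5)), np.array([0, 7, 1]))


class TestSchedule:
    def test_printed_schedule_values(self):
        cfg = TrainConfig()
        assert lr_at_epoch(0, cfg) == pytest.approx(1e-4)
        assert lr_at_epoch(5, cfg) == pytest.approx(5e-5)
        assert lr_at_epoch(12, cfg) == pytest.approx(2.5e-5)

    def test_twenty_epoch_sequence_in_blocks_of_five(self):
        cfg = TrainConfig()
        got = [lr_at_epoch(t, cfg) for t in range(20)]
        want = [1e-4] * 5 + [5e-5] * 5 + [2.5e-5] * 5 + [1.25e-5] * 5
        np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_negative_epoch_rejected(self):
        with pytest.raises(ParameterError):
            lr_at_epoch(-1, TrainConfig())


class TestTrainConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"lr": -1.0},
            {"gamma": 0.0},
            {"gamma": 1.5},
            {"batch_size": 0},
            {"loss_weights": (0, 0, 0)},
            {"monitor": "f1"},
        ],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            TrainConfig(**kwargs)


def _toy_problem(rng, n_subjects=3, n=90, w=64):
    """Trivially separable windows: each subject has a distinct DC pattern."""
    X = rng.normal(size=(n, 4, w)).astype(np.float32) * 0.05
    y = {
        "bio": rng.integers(0, n_subjects, n),
        "lang": rng.integers(0, 2, n),
        "dev": rng.integers(0, 2, n),
    }
    for i in range(n):
        X[i, y["bio"][i] % 4] += 1.0
        X[i] += 0.5 * y["lang"][i] * np.sin(np.arange(w) / 3)
        X[i] += 0.5 * y["dev"][i] * np.cos(np.arange(w) / 7)
    return X, y


@pytest.fixture
def toy_config():
    return ModelConfig(
        conv_channels=(8, 16), d_model=16, n_layers=1, n_heads=2, ffn_dim=32,
        dropout=0.0, head_hidden=8, n_subjects=3, max_seq_len=32,
    )


class TestTrainLoop:
    def test_loss_decreases_on_separable_toy(self, toy_config, rng):
        X, y = _toy_problem(rng)
        m = build_model(toy_config, "full", seed=0)
        cfg = TrainConfig(lr=1e-3, epochs=5, patience=5, seed=0)
        m, hist = train(m, (X[:60], {k: v[:60] for k, v in y.items()}),
                        (X[60:], {k: v[60:] for k, v in y.items()}), cfg)
        assert hist.epochs[-1]["train_loss"] < hist.epochs[0]["train_loss"]
        assert hist.epochs[0]["lr"] == pytest.approx(1e-3)

    def test_same_seed_identical_histories(self, toy_config, rng):
        X, y = _toy_problem(rng)
        tr = (X[:60], {k: v[:60] for k, v in y.items()})
        va = (X[60:], {k: v[60:] for k, v in y.items()})
        hists = []
        for _ in range(2):
            m = build_model(toy_config, "full", seed=5)
            cfg = TrainConfig(lr=1e-3, epochs=3, seed=5)
            _, h = train(m, tr, va, cfg)
            hists.append(h)
        a, b = hists
        assert a.n_epochs == b.n_epochs
        for ra, rb in zip(a.epochs, b.epochs):
            assert ra == rb

    def test_different_seeds_differ_at_init(self, toy_config):
        m1 = build_model(toy_config, "full", seed=7)
        m2 = build_model(toy_config, "full", seed=8)
        assert not np.array_equal(m1.conv1.W.data, m2.conv1.W.data)

    def test_zero_patience_stops_at_first_non_improvement(self, toy_config, rng):
        X, y = _toy_problem(rng)
        tr = (X[:60], {k: v[:60] for k, v in y.items()})
        va = (X[60:], {k: v[60:] for k, v in y.items()})
        m = build_model(toy_config, "full", seed=0)
        # lr=0 freezes the model: the monitor can never improve after epoch 0
        cfg = TrainConfig(lr=1e-30, epochs=10, patience=0, seed=0)
        _, hist = train(m, tr, va, cfg)
        assert hist.stopped_early
        assert hist.best_epoch == 0
        assert hist.n_epochs == 2

    def test_best_epoch_monitor_is_maximal(self, toy_config, rng):
        X, y = _toy_problem(rng)
        tr = (X[:60], {k: v[:60] for k, v in y.items()})
        va = (X[60:], {k: v[60:] for k, v in y.items()})
        m = build_model(toy_config, "full", seed=1)
        cfg = TrainConfig(lr=1e-3, epochs=6, patience=6, seed=1)
        _, hist = train(m, tr, va, cfg)
        monitors = [r["monitor"] for r in hist.epochs]
        assert monitors[hist.best_epoch] == max(monitors)

    def test_empty_split_rejected(self, toy_config, rng):
        X, y = _toy_problem(rng)
        m = build_model(toy_config, "full", seed=0)
        with pytest.raises(ParameterError):
            train(m, (X[:0], {k: v[:0] for k, v in y.items()}),
                  (X, y), TrainConfig())

    def test_history_lr_column_matches_schedule(self, toy_config, rng):
        X, y = _toy_problem(rng)
        tr = (X[:60], {k: v[:60] for k, v in y.items()})
        va = (X[60:], {k: v[60:] for k, v in y.items()})
        m = build_model(toy_config, "full", seed=0)
        cfg = TrainConfig(lr=1e-3, epochs=7, step_size=2, gamma=0.5, patience=7, seed=0)
        _, hist = train(m, tr, va, cfg)
        for row in hist.epochs:
            assert row["lr"] == pytest.approx(lr_at_epoch(row["epoch"], cfg))


def test_set_global_seed_is_recorded():
    set_global_seed(123)
    from eegmtl.training import get_global_seed

    assert get_global_seed() == 123
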