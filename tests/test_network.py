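import numpy as np
import pytest

from apneafusion import (
    NetworkSpec,
    TrainingConfig,
    build_network,
    cross_entropy,
    predict,
    select_best_checkpoint,
    softmax,
    train,
)
from apneafusion.network import (
    EvalRecord,
    Network,
    TrainingHistory,
    load_network,
    save_network,
    softmax_cross_entropy_grad,
)
from conftest import make_separable_images

TINY = dict(
    input_shape=(16, 16, 3), stem_filters=4, block_filters=(4, 8), dense_units=16
)


class TestArchitecture:
    def test_thirteen_convolutions(self):
        assert build_network(2).layer_census()["conv"] == 13

    def test_four_pooling_layers(self):
        assert build_network(2).layer_census()["maxpool"] == 4

    def test_feature_map_before_flatten(self):
        assert build_network(2).feature_map_shape == (8, 8, 128)

    def test_block_filter_progression(self):
        spec = build_network(2)
        conv_filters = [l.filters for l in spec.layers if l.kind == "conv" and not l.skip]
        assert conv_filters == [32, 32, 32, 64, 64, 96, 96, 128, 128]
        skips = [l.filters for l in spec.layers if l.skip]
        assert skips == [32, 64, 96, 128]

    def test_unknown_override_rejected(self):
        with pytest.raises(ValueError):
            build_network(2, {"n_wheels": 4})

    def test_collapsing_input_rejected(self):
        with pytest.raises(ValueError):
            build_network(2, {"input_shape": (8, 8, 3)})  # 4 pools halve to 0

    def test_num_classes_validated(self):
        with pytest.raises(ValueError):
            build_network(1)

    def test_forward_output_dimension(self):
        spec = build_network(3, TINY)
        net = Network(spec, seed=0)
        out = net.forward(np.zeros((2, 16, 16, 3), np.float32))
        assert out.shape == (2, 3)


class TestSoftmax:
    def test_equal_activations_uniform(self):
        assert np.allclose(softmax([0.0, 0.0]), [0.5, 0.5])

    def test_log_two_ratio(self):
        assert np.allclose(softmax([np.log(2), 0.0]), [2 / 3, 1 / 3])

    def test_shift_invariance(self):
        a = np.array([0.3, -1.2, 5.0])
        assert np.allclose(softmax(a), softmax(a + 123.4))

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            softmax([np.nan, 0.0])


class TestCrossEntropy:
    def test_perfect_prediction_zero_loss(self):
        assert cross_entropy([[1.0, 0.0], [0.0, 1.0]], [[1, 0], [0, 1]]) == pytest.approx(0.0)

    def test_uniform_predictions_n_ln2(self):
        n = 7
        pred = np.full((n, 2), 0.5)
        tgt = np.eye(2)[np.zeros(n, int)]
        assert cross_entropy(pred, tgt) == pytest.approx(n * np.log(2))

    def test_single_example_closed_form(self):
        assert cross_entropy([[0.9, 0.1]], [[1, 0]]) == pytest.approx(-np.log(0.9), abs=1e-9)

    def test_unnormalized_rows_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy([[0.9, 0.9]], [[1, 0]])


def test_gradient_check_small_network():
    """Numerical vs analytic gradient of the summed cross-entropy through a
    reduced network agrees to 1e-4 relative error."""
    spec = build_network(
        2,
        {
            "input_shape": (8, 8, 3),
            "stem_filters": 4,
            "block_filters": (4, 8),
            "dense_units": 16,
            "dropout_rate": 0.0,
        },
    )
    net = Network(spec, seed=3, dtype=np.float64)
    rng = np.random.default_rng(0)
    x = rng.random((3, 8, 8, 3))
    y = np.array([0, 1, 1])

    def loss_fn():
        return softmax_cross_entropy_grad(net.forward(x), y)

    _, d = loss_fn()
    net.backward(d)
    for p in net.parameters():
        analytic = p.grad.copy().reshape(-1)
        flat = p.value.reshape(-1)
        for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
            old = flat[i]
            flat[i] = old + 1e-6
            lp, _ = loss_fn()
            flat[i] = old - 1e-6
            lm, _ = loss_fn()
            flat[i] = old
            numeric = (lp - lm) / 2e-6
            denom = max(abs(numeric), abs(analytic[i]), 1e-8)
            assert abs(numeric - analytic[i]) / denom < 1e-4


class TestTraining:
    def test_loss_decreases_on_separable_data(self):
        X, labels = make_separable_images(20, 16, seed=1)
        y = (labels == "A").astype(int)
        cfg = TrainingConfig(batch_size=8, max_epochs=5, eval_interval=5, seed=0)
        _, hist = train(build_network(2, TINY), X, y, X[:8], y[:8], cfg)
        assert hist.records[-1].train_loss < hist.records[0].train_loss

    def test_shuffled_labels_stay_near_chance(self):
        X, _ = make_separable_images(30, 16, seed=2)
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, len(X))
        val_X, val_y = X[:20], y[:20]
        cfg = TrainingConfig(batch_size=8, max_epochs=3, eval_interval=64, seed=0)
        _, hist = train(build_network(2, TINY), X[20:], y[20:], val_X, val_y, cfg)
        assert 0.25 <= hist.records[-1].val_accuracy <= 0.75

    def test_deterministic_runs_identical(self):
        X, labels = make_separable_images(10, 16, seed=4)
        y = (labels == "A").astype(int)
        cfg = TrainingConfig(batch_size=8, max_epochs=2, eval_interval=2, seed=42)
        _, h1 = train(build_network(2, TINY), X, y, X[:6], y[:6], cfg)
        _, h2 = train(build_network(2, TINY), X, y, X[:6], y[:6], cfg)
        assert [r.__dict__ for r in h1.records] == [r.__dict__ for r in h2.records]

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            train(build_network(2, TINY), np.zeros((0, 16, 16, 3)), [], np.zeros((1, 16, 16, 3)), [0])


class TestCheckpointSelection:
    def _history(self, accs):
        h = TrainingHistory()
        for i, a in enumerate(accs):
            h.add(EvalRecord(iteration=i + 1, train_loss=1.0, val_loss=1.0,
                             val_accuracy=a, checkpoint_id=i), [])
        return h

    def test_max_accuracy_selected(self):
        assert select_best_checkpoint(self._history([0.7, 0.9, 0.8])) == 1

    def test_tie_goes_to_earliest(self):
        assert select_best_checkpoint(self._history([0.9, 0.9])) == 0

    def test_single_evaluation(self):
        assert select_best_checkpoint(self._history([0.4])) == 0

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            select_best_checkpoint(TrainingHistory())


class TestPredict:
    def test_rows_sum_to_one_and_duplicates_match(self):
        net = Network(build_network(2, TINY), seed=0)
        img = np.random.default_rng(0).random((1, 16, 16, 3)).astype(np.float32)
        batch = np.concatenate([img, img])
        probs, labels = predict(net, batch)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.allclose(probs[0], probs[1])
        assert labels.shape == (2,)

    def test_zeroed_final_layer_gives_uniform(self):
        net = Network(build_network(2, TINY), seed=0)
        net.fc2.w.value[...] = 0
        net.fc2.b.value[...] = 0
        probs, _ = predict(net, np.random.default_rng(1).random((3, 16, 16, 3)).astype(np.float32))
        assert np.allclose(probs, 0.5, atol=1e-6)

    def test_shape_mismatch_rejected(self):
        net = Network(build_network(2, TINY), seed=0)
        with pytest.raises(ValueError):
            net.forward(np.zeros((1, 8, 8, 3), np.float32))


def test_save_load_roundtrip(tmp_path):
    net = Network(build_network(2, TINY), seed=5)
    x = np.random.default_rng(2).random((2, 16, 16, 3)).astype(np.float32)
    p1, _ = predict(net, x)
    save_network(net, tmp_path / "m.npz")
    p2, _ = predict(load_network(tmp_path / "m.npz"), x)
    assert np.allclose(p1, p2)
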