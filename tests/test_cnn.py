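"""The 3D CNN: shape contract, gradients, training, inference purity."""

import numpy as np
import pytest

from nodulefuse.cnn import (
    ArchitectureSpec,
    MaligNet,
    TrainConfig,
    _Conv3D,
    _Dense,
    _MaxPool3D,
    build_model,
    normalize_boxes,
    train,
)
from nodulefuse.exceptions import ConfigurationError, TrainingError


def _size_cohort(n, seed, big_frac=0.5):
    """Boxes whose class is carried by blob size (size-driven toy task)."""
    rng = np.random.default_rng(seed)
    boxes = rng.normal(0, 1, size=(n, 32, 32, 16)).astype(np.float32)
    labels = (rng.uniform(size=n) < big_frac).astype(int)
    c = [np.arange(s) - (s - 1) / 2 for s in (32, 32, 16)]
    xx, yy, zz = np.meshgrid(*c, indexing="ij")
    for i in range(n):
        r = 6.0 if labels[i] else 3.0
        boxes[i][xx**2 + yy**2 + zz**2 <= r**2] += 3.0
    return normalize_boxes(boxes), labels


class TestArchitecture:
    def test_parameter_count_matches_hand_audit(self):
        # closed-form sum over the declared layers, computed once by hand
        assert ArchitectureSpec().parameter_count() == 16_294_817
        assert build_model(ArchitectureSpec().scaled(8)).parameter_count() == \
            ArchitectureSpec().scaled(8).parameter_count()

    def test_spatial_trace(self):
        assert ArchitectureSpec().spatial_trace == [
            (32, 32, 16), (16, 16, 8), (8, 8, 4), (4, 4, 2), (2, 2, 1),
        ]

    def test_final_conv_stack_output_shape(self):
        # the conv stack must end at 2x2x1 with 512 channels
        model = build_model(ArchitectureSpec(), seed=0)
        x = np.zeros((1, 1, 32, 32, 16), dtype=np.float32)
        for layer in model.layers:
            if type(layer).__name__ == "_Flatten":
                break
            x = layer.forward(x, train=False)
        assert x.shape == (1, 512, 2, 2, 1)

    def test_forward_on_zero_box_is_finite_probability(self):
        model = build_model(ArchitectureSpec(), seed=0)
        score = model.predict_scores(np.zeros((32, 32, 16), dtype=np.float32))
        assert np.isfinite(score[0]) and 0.0 <= score[0] <= 1.0

    def test_wrong_input_shape_rejected(self):
        model = build_model(ArchitectureSpec().scaled(8))
        with pytest.raises(ConfigurationError):
            model.predict_scores(np.zeros((16, 16, 8), dtype=np.float32))

    def test_penultimate_width_is_locked(self):
        with pytest.raises(ConfigurationError):
            ArchitectureSpec(dense=(128, 32, 1))


class TestGradients:
    """Analytic backprop vs central finite differences on tiny layers."""

    @staticmethod
    def _num_grad(f, x, eps=1e-6):
        g = np.zeros_like(x, dtype=np.float64)
        it = np.nditer(x, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            orig = x[i]
            x[i] = orig + eps
            hi = f()
            x[i] = orig - eps
            lo = f()
            x[i] = orig
            g[i] = (hi - lo) / (2 * eps)
        return g

    @staticmethod
    def _to_float64(layer):
        layer.w = layer.w.astype(np.float64)
        layer.b = layer.b.astype(np.float64)
        layer.gw = np.zeros_like(layer.w)
        layer.gb = np.zeros_like(layer.b)

    def test_conv3d_gradients(self):
        rng = np.random.default_rng(0)
        layer = _Conv3D(2, 3, rng, l2=0.0)
        self._to_float64(layer)
        x = rng.normal(size=(2, 2, 3, 3, 2))
        w = rng.normal(size=(3, 3, 3, 2))  # random linear loss weights

        def loss():
            return float((layer.forward(x, train=False) * w[None]).sum())

        out = layer.forward(x, train=True)
        dx = layer.backward(np.broadcast_to(w[None], out.shape).copy())
        assert np.allclose(dx, self._num_grad(loss, x), atol=1e-6)
        assert np.allclose(layer.gw, self._num_grad(loss, layer.w), atol=1e-6)
        assert np.allclose(layer.gb, self._num_grad(loss, layer.b), atol=1e-6)

    def test_dense_gradients(self):
        rng = np.random.default_rng(1)
        layer = _Dense(5, 4, rng, l2=0.0)
        self._to_float64(layer)
        x = rng.normal(size=(3, 5))
        w = rng.normal(size=(3, 4))

        def loss():
            return float((layer.forward(x, train=False) * w).sum())

        layer.forward(x, train=True)
        dx = layer.backward(w)
        assert np.allclose(dx, self._num_grad(loss, x), atol=1e-6)
        assert np.allclose(layer.gw, self._num_grad(loss, layer.w), atol=1e-6)

    def test_maxpool_routes_gradient_to_argmax(self):
        pool = _MaxPool3D()
        x = np.arange(2 * 1 * 4 * 4 * 2, dtype=np.float32).reshape(2, 1, 4, 4, 2)
        out = pool.forward(x, train=True)
        dout = np.ones_like(out)
        dx = pool.backward(dout)
        assert dx.sum() == out.size
        # gradient lands exactly on the per-window maxima
        assert (dx[x == x.max()] == 1).all()
        assert (dx.reshape(-1)[:2] == 0).all()


class TestTraining:
    def test_zero_learning_rate_is_a_no_op(self, narrow_arch):
        model = build_model(narrow_arch, seed=1)
        before = [p.copy() for p, _ in model.params]
        boxes, labels = _size_cohort(8, seed=0)
        history = train(model, boxes, labels, TrainConfig(epochs=2, learning_rate=0.0))
        for (p, _), b in zip(model.params, before):
            assert (p == b).all()
        assert history["loss"][0] == pytest.approx(history["loss"][1], rel=1e-5)

    def test_single_class_labels_rejected(self, narrow_arch):
        model = build_model(narrow_arch)
        boxes, _ = _size_cohort(6, seed=0)
        with pytest.raises(TrainingError):
            train(model, boxes, np.ones(6), TrainConfig(epochs=1))

    def test_memorizes_small_sample(self, narrow_arch):
        from nodulefuse.evaluate import roc_auc

        boxes, labels = _size_cohort(32, seed=3)
        model = build_model(narrow_arch, seed=2)
        train(model, boxes, labels,
              TrainConfig(epochs=40, batch_size=8, learning_rate=1e-3, seed=0))
        auc = roc_auc(model.predict_scores(boxes), labels).auc
        assert auc >= 0.99

    def test_beats_chance_on_held_out_size_task(self, narrow_arch):
        from nodulefuse.evaluate import roc_auc

        aucs = []
        for seed in range(5):
            boxes, labels = _size_cohort(160, seed=10 + seed)
            model = build_model(narrow_arch, seed=seed)
            train(model, boxes[:120], labels[:120],
                  TrainConfig(epochs=4, batch_size=8, learning_rate=1e-3, seed=seed))
            aucs.append(roc_auc(model.predict_scores(boxes[120:]), labels[120:]).auc)
        mean = float(np.mean(aucs))
        se = float(np.std(aucs, ddof=1) / np.sqrt(len(aucs)))
        assert mean > 0.5 + 3 * se

    def test_seeded_training_reproducible(self, narrow_arch):
        boxes, labels = _size_cohort(16, seed=5)
        runs = []
        for _ in range(2):
            model = build_model(narrow_arch, seed=4)
            train(model, boxes, labels, TrainConfig(epochs=2, batch_size=8, seed=1))
            runs.append(model.predict_scores(boxes))
        assert (runs[0] == runs[1]).all()


@pytest.fixture(scope="module")
def trained(narrow_arch):
    boxes, labels = _size_cohort(24, seed=7)
    model = build_model(narrow_arch, seed=3)
    train(model, boxes, labels, TrainConfig(epochs=3, batch_size=8, seed=0))
    return model


class TestInference:
    def test_repeated_prediction_bitwise_identical(self, trained):
        boxes, _ = _size_cohort(4, seed=9)
        assert (trained.predict_scores(boxes) == trained.predict_scores(boxes)).all()

    def test_batching_invariance(self, trained):
        boxes, _ = _size_cohort(12, seed=10)
        one = np.concatenate([trained.predict_scores(b) for b in boxes])
        batched = trained.predict_scores(boxes, batch_size=12)
        assert np.allclose(one, batched, atol=1e-5)

    def test_scores_stay_in_unit_interval(self, trained):
        rng = np.random.default_rng(11)
        boxes = rng.normal(size=(200, 32, 32, 16)).astype(np.float32) * 5
        scores = trained.predict_scores(boxes)
        assert ((scores >= 0) & (scores <= 1)).all()

    def test_feature_vector_length_and_nonnegativity(self, trained):
        boxes, _ = _size_cohort(6, seed=12)
        feats = trained.extract_features(boxes)
        assert feats.shape == (6, 64)
        assert (feats >= 0).all()  # ReLU penultimate layer

    def test_distinct_boxes_give_distinct_features(self, trained):
        boxes, _ = _size_cohort(8, seed=13)
        feats = trained.extract_features(boxes)
        for i in range(len(feats)):
            for j in range(i + 1, len(feats)):
                assert not np.array_equal(feats[i], feats[j])

    def test_save_load_round_trip(self, trained, tmp_path):
        boxes, _ = _size_cohort(4, seed=14)
        prefix = str(tmp_path / "model")
        trained.save(prefix)
        loaded = MaligNet.load(prefix)
        assert (loaded.predict_scores(boxes) == trained.predict_scores(boxes)).all()
        assert loaded.spec == trained.spec
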