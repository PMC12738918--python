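"""Network engine gradients, architecture construction and training behaviour."""

import numpy as np
import pytest

from weedspec import nn
from weedspec.errors import ConstructionError, ParameterError, ShapeMismatchError
from weedspec.patch_dataset import PatchSet
from weedspec.sscnn import (
    ModelConfig,
    TrainedModel,
    build_model,
    build_network,
    predict_map,
    softsign,
    train,
)
from weedspec.superpixel import ReducedCube

rng0 = np.random.default_rng(0)


class TestSoftsign:
    @pytest.mark.parametrize("x,expected", [(0.0, 0.0), (1.0, 0.5), (-3.0, -0.75)])
    def test_values(self, x, expected):
        assert softsign(x) == expected

    def test_odd_and_bounded(self):
        x = np.linspace(-50, 50, 101)
        y = softsign(x)
        np.testing.assert_allclose(softsign(-x), -y)
        assert np.all(np.abs(y) < 1.0)


def _num_grad(f, arr, eps=1e-6):
    g = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = arr[i]
        arr[i] = old + eps
        fp = f()
        arr[i] = old - eps
        fm = f()
        arr[i] = old
        g[i] = (fp - fm) / (2 * eps)
    return g


def _check_layer(layer, x, tol=1e-5):
    rng = np.random.default_rng(7)
    tgt = rng.normal(size=layer.forward(x.copy(), True).shape)

    def loss():
        return 0.5 * np.sum((layer.forward(x, True) - tgt) ** 2)

    out = layer.forward(x, True)
    dx = layer.backward(out - tgt)
    assert np.max(np.abs(_num_grad(loss, x) - dx)) < tol
    for k, p in layer.params.items():
        layer.backward(layer.forward(x, True) - tgt)
        assert np.max(np.abs(_num_grad(loss, p) - layer.grads[k])) < tol, k


class TestGradients:
    """Analytic backward passes agree with central finite differences."""

    def test_conv3d(self):
        _check_layer(nn.Conv3D(2, 3, (3, 3, 3), rng0), rng0.normal(size=(2, 4, 4, 5, 2)))

    def test_conv2d(self):
        _check_layer(nn.Conv2D(3, 4, (3, 3), rng0), rng0.normal(size=(2, 5, 5, 3)))

    def test_batchnorm(self):
        _check_layer(nn.BatchNorm(3), rng0.normal(size=(4, 3, 3, 3)))

    def test_se_block(self):
        _check_layer(nn.SEBlock(4, 2, rng0), rng0.normal(size=(2, 3, 3, 4)))

    def test_dense_and_activations(self):
        _check_layer(nn.Dense(5, 3, rng0), rng0.normal(size=(4, 5)))
        _check_layer(nn.Activation("softsign"), rng0.normal(size=(3, 4)))

    def test_softmax_cross_entropy_gradient(self):
        logits = rng0.normal(size=(5, 3))
        onehot = np.eye(3)[[0, 1, 2, 1, 0]]
        _, g = nn.softmax_cross_entropy(logits, onehot)

        def loss():
            return nn.softmax_cross_entropy(logits, onehot)[0]

        assert np.max(np.abs(_num_grad(loss, logits) - g)) < 1e-6


class TestSEBlockSemantics:
    def test_zero_weights_gate_half(self):
        se = nn.SEBlock(4, 2, rng0)
        for k in se.params:
            se.params[k] = np.zeros_like(se.params[k])
        x = rng0.normal(size=(2, 3, 3, 4))
        np.testing.assert_allclose(se.forward(x, False), 0.5 * x)

    def test_shape_preserved_and_gates_bounded(self):
        se = nn.SEBlock(8, 4, rng0)
        x = rng0.normal(size=(3, 5, 5, 8))
        out = se.forward(x, False)
        assert out.shape == x.shape
        assert np.all(se._gate > 0) and np.all(se._gate < 1)

    def test_channel_constant_squeeze(self):
        se = nn.SEBlock(4, 2, rng0)
        x = np.ones((1, 3, 3, 4)) * np.array([1.0, 2.0, 3.0, 4.0])
        se.forward(x, False)
        np.testing.assert_allclose(se._z, [[1.0, 2.0, 3.0, 4.0]])

    def test_channel_mismatch(self):
        se = nn.SEBlock(4, 2, rng0)
        with pytest.raises(ShapeMismatchError):
            se.forward(np.zeros((1, 3, 3, 5)), False)


class TestArchitecture:
    def test_full_model_layer_anchors(self):
        """Printed layer summary of the 25x25x25 network, from first principles."""
        spec = build_model(ModelConfig())
        assert spec.layer("conv3d_1").params == 512
        assert spec.layer("conv3d_1").output_shape == (23, 23, 19, 8)
        assert spec.layer("conv3d_2").params == 5776
        assert spec.layer("conv3d_2").output_shape == (21, 21, 15, 16)
        assert spec.layer("conv3d_3").params == 13856
        assert spec.layer("conv3d_3").output_shape == (19, 19, 13, 32)
        assert spec.layer("reshape").output_shape == (19, 19, 416)
        assert spec.layer("conv2d_1").params == 119840
        assert spec.layer("conv2d_1").output_shape == (17, 17, 32)
        assert spec.layer("head").output_shape == (36,)

    def test_shape_chain_shrinks_by_kernel_minus_one(self):
        spec = build_model(ModelConfig())
        prev = spec.layer("input").output_shape
        for i, k in enumerate(((3, 3, 7), (3, 3, 5), (3, 3, 3)), 1):
            cur = spec.layer(f"conv3d_{i}").output_shape
            assert cur[:3] == tuple(p - (kk - 1) for p, kk in zip(prev[:3], k))
            prev = cur

    def test_variant_module_presence(self):
        kinds = lambda cfg: {li.kind for li in build_model(cfg).layers}
        small = dict(
            window=9, bands=8, n_classes=6, conv3d_filters=(4, 8),
            conv3d_kernels=((3, 3, 5), (3, 3, 3)), conv2d_filters=(8, 16),
            dense_units=(32,), se_reduction=4,
        )
        assert "conv3d" not in kinds(ModelConfig(variant="CNN2D", **small))
        assert "conv2d" not in kinds(ModelConfig(variant="CNN3D", **small))
        assert "se" not in kinds(ModelConfig(variant="SD", **small))
        assert "se" in kinds(ModelConfig(variant="SE", **small))
        ss = kinds(ModelConfig(variant="SS", **small))
        assert {"conv3d", "conv2d", "se"} <= ss

    def test_spec_counts_match_instantiated_network(self):
        small = dict(
            window=9, bands=8, n_classes=6, conv3d_filters=(4, 8),
            conv3d_kernels=((3, 3, 5), (3, 3, 3)), conv2d_filters=(8, 16),
            dense_units=(32,), se_reduction=4,
        )
        for variant in ("SS", "SD", "SE", "CNN3D", "CNN2D"):
            cfg = ModelConfig(variant=variant, **small)
            spec = build_model(cfg)
            net = build_network(cfg)  # raises on mismatch by contract
            assert sum(ly.n_params for ly in net.layers) == spec.total_params

    def test_hand_counted_small_conv3d(self):
        cfg = ModelConfig(
            variant="CNN3D", window=5, bands=6, n_classes=2,
            conv3d_filters=(3,), conv3d_kernels=((3, 3, 3),), dense_units=(4,),
        )
        spec = build_model(cfg)
        # 3 filters * (3*3*3 kernel * 1 input map) + 3 biases
        assert spec.layer("conv3d_1").params == 3 * 27 + 3

    def test_window_too_small_raises(self):
        with pytest.raises(ConstructionError):
            build_model(ModelConfig(window=5))

    def test_se_reduction_must_divide_channels(self):
        with pytest.raises(ConstructionError):
            build_model(ModelConfig(se_reduction=17))

    def test_invalid_variant(self):
        with pytest.raises(ParameterError):
            ModelConfig(variant="YOLO")


def _separable_patchset(n_per_class=20, w=5, b=4, gap=3.0, seed=0):
    rng = np.random.default_rng(seed)
    windows, labels = [], []
    for cls in (1, 2):
        level = (cls - 1) * gap
        windows.append(level + rng.normal(0, 0.3, size=(n_per_class, w, w, b)))
        labels.append(np.full(n_per_class, cls))
    return PatchSet(
        windows=np.concatenate(windows),
        centers=np.zeros((2 * n_per_class, 2), dtype=int),
        labels=np.concatenate(labels),
        n_classes=2,
    )


_toy_cfg = dict(
    window=5, bands=4, n_classes=2, conv3d_filters=(2,),
    conv3d_kernels=((3, 3, 3),), conv2d_filters=(4,), dense_units=(8,),
    se_reduction=2, dropout=0.2, lr=3e-3, epochs=50, batch_size=8,
)


class TestTraining:
    def test_separable_toy_fits_exactly(self):
        """An over-parameterized net drives training OA to 100% on separable data."""
        ps = _separable_patchset()
        model = train(ModelConfig(variant="SS", seed=0, **_toy_cfg), ps)
        assert model.history.train_oa.iloc[-1] == 1.0
        assert model.history.loss.iloc[-1] <= model.history.loss.iloc[0]

    def test_same_seed_identical_loss(self):
        ps = _separable_patchset()
        cfg = ModelConfig(variant="SS", seed=5, **{**_toy_cfg, "epochs": 3})
        a = train(cfg, ps)
        b = train(cfg, ps)
        assert a.history.loss.iloc[-1] == b.history.loss.iloc[-1]

    def test_empty_train_set_raises(self):
        ps = _separable_patchset(n_per_class=1)
        from weedspec.errors import EmptySelectionError

        with pytest.raises(EmptySelectionError):
            train(ModelConfig(variant="SS", seed=0, **_toy_cfg), ps.subset(np.array([], int)))

    def test_save_load_roundtrip(self, tmp_path):
        ps = _separable_patchset()
        cfg = ModelConfig(variant="SS", seed=1, **{**_toy_cfg, "epochs": 2})
        model = train(cfg, ps)
        model.save(tmp_path / "ckpt.npz")
        back = TrainedModel.load(tmp_path / "ckpt.npz")
        np.testing.assert_array_equal(
            model.predict_labels(ps.windows), back.predict_labels(ps.windows)
        )


class TestPredictMap:
    def _scene(self):
        rng = np.random.default_rng(3)
        labels = np.zeros((10, 10), dtype=int)
        labels[:, :5] = 1
        labels[:, 5:] = 2
        values = np.where(labels[:, :, None] == 2, 3.0, 0.0) + rng.normal(
            0, 0.3, (10, 10, 4)
        )
        rc = ReducedCube(
            values=values, loadings=np.eye(4), mean=np.zeros(4),
            explained_pct=np.zeros(4),
        )
        return rc, labels

    def test_probabilities_and_argmax_consistency(self):
        rc, labels = self._scene()
        from weedspec.patch_dataset import extract_patches

        ps = extract_patches(rc, labels, w=5)
        model = train(ModelConfig(variant="SS", seed=0, **_toy_cfg), ps)
        pred, probs = predict_map(model, rc)
        np.testing.assert_allclose(probs.sum(axis=2), 1.0, atol=1e-6)
        np.testing.assert_array_equal(pred, np.argmax(probs, axis=2) + 1)

    def test_separable_scene_recovered(self):
        rc, labels = self._scene()
        from weedspec.patch_dataset import extract_patches

        ps = extract_patches(rc, labels, w=5)
        model = train(ModelConfig(variant="SS", seed=0, **_toy_cfg), ps)
        pred, _ = predict_map(model, rc)
        assert np.mean(pred == labels) == 1.0

    def test_band_mismatch_raises(self):
        rc, labels = self._scene()
        from weedspec.patch_dataset import extract_patches

        ps = extract_patches(rc, labels, w=5)
        model = train(ModelConfig(variant="SS", seed=0, **{**_toy_cfg, "epochs": 1}), ps)
        bad = ReducedCube(
            values=np.zeros((6, 6, 3)), loadings=np.eye(3), mean=np.zeros(3),
            explained_pct=np.zeros(3),
        )
        with pytest.raises(ShapeMismatchError):
            predict_map(model, bad)
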