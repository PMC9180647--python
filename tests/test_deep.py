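"""Architecture contracts, gradient correctness, and training behavior of the
NumPy spectral networks."""

import numpy as np
import pytest

import grapesense as gs
from grapesense.deep import (
    CnnSpec,
    ResNetSpec,
    TrainConfig,
    build_cnn,
    build_resnet,
    train_model,
)
from grapesense.nn import ResidualBlock, softmax_cross_entropy
from grapesense.nn.layers import ArchitectureError


def flatten_width(net):
    return [shape for name, shape, _ in net.summary if name == "Flatten"][0][0]


class TestCnnArchitecture:
    def test_stage_lengths_at_80_bands(self):
        net = build_cnn(80)
        conv_shapes = [s for n, s, _ in net.summary if n == "Conv1d"]
        assert conv_shapes == [(128, 80), (64, 80), (32, 78)]
        pool = [s for n, s, _ in net.summary if n == "AvgPool1d"][0]
        assert pool == (32, 39)
        assert flatten_width(net) == 1248

    def test_stage_lengths_at_230_bands(self):
        net = build_cnn(230)
        assert flatten_width(net) == 3648

    def test_boundary_band_counts(self):
        assert flatten_width(build_cnn(4)) == 32  # conv3 shrinks 4 -> 2, pool -> 1
        with pytest.raises(ArchitectureError):
            build_cnn(2)

    def test_parameter_count_matches_layer_by_layer_sum(self):
        # independent sum: conv (out*in*k + out), BN (2*features),
        # linear (out*in + out); dropout/pool/relu carry none
        conv = lambda o, i, k: o * i * k + o
        lin = lambda o, i: o * i + o
        expected = (
            conv(128, 1, 3) + 2 * 128
            + conv(64, 128, 3) + 2 * 64
            + conv(32, 64, 5) + 2 * 32
            + lin(256, 32 * 39) + 2 * 256
            + lin(128, 256) + 2 * 128
            + lin(4, 128)
        )
        assert build_cnn(80).param_count() == expected


class TestResNetArchitecture:
    def test_pooled_feature_width_is_256_for_any_band_count(self):
        for n_bands in (16, 80, 230):
            net = build_resnet(n_bands)
            pooled = [s for n, s, _ in net.summary if n == "GlobalAvgPool1d"][0]
            assert pooled == (256,)

    def test_parameter_count_matches_layer_by_layer_sum(self):
        conv = lambda o, i, k: o * i * k + o
        block_same = conv(64, 64, 3) * 2 + 2 * 64 * 2          # identity skip
        block_64_128 = (conv(128, 64, 3) + conv(128, 128, 3) + 2 * 128 * 2
                        + conv(128, 64, 1) + 2 * 128)          # projected skip
        block_128_256 = (conv(256, 128, 3) + conv(256, 256, 3) + 2 * 256 * 2
                         + conv(256, 128, 1) + 2 * 256)
        expected = (conv(64, 1, 3) + 2 * 64 + block_same + block_64_128
                    + block_128_256 + (256 * 4 + 4))
        assert build_resnet(80).param_count() == expected

    def test_zero_weight_block_is_identity(self):
        rng = np.random.default_rng(0)
        blk = ResidualBlock(8, 8, 3, 1, rng)
        for conv, bn in ((blk.conv1, blk.bn1), (blk.conv2, blk.bn2)):
            conv.params["W"][:] = 0.0
            conv.params["b"][:] = 0.0
        x = np.abs(rng.standard_normal((2, 8, 12))).astype(np.float32)
        out = blk.forward(x, training=False, rng=rng)
        np.testing.assert_allclose(out, x, atol=1e-6)

    def test_too_few_bands_rejected(self):
        with pytest.raises(ArchitectureError):
            build_resnet(3)


class TestGradients:
    def test_input_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((2, 16))
        net = build_cnn(16, seed=1)
        net.forward(rng.standard_normal((16, 16)), training=True)  # warm BN stats
        cls = np.array([0, 2])
        g = net.score_input_gradient(X, cls)
        eps = 1e-5
        for i in range(2):
            for j in range(0, 16, 3):
                xp, xm = X.copy(), X.copy()
                xp[i, j] += eps
                xm[i, j] -= eps
                fd = (net.class_scores(xp)[i, cls[i]]
                      - net.class_scores(xm)[i, cls[i]]) / (2 * eps)
                assert abs(g[i, j] - fd) <= 1e-3 * max(abs(fd), 1e-8)

    def test_evaluation_is_deterministic(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((5, 20))
        net = build_cnn(20, seed=2)
        np.testing.assert_array_equal(net.class_scores(X), net.class_scores(X))


class TestTraining:
    @staticmethod
    def _quick_ds(n_per_class=20, n_bands=16, **cfg_over):
        cfg = gs.SceneConfig(
            wavelength_grid=np.linspace(476, 890, n_bands),
            class_counts={"Cabernet": (n_per_class,) * 4},
            peak_depths=(0.0, 0.1, 0.2, 0.4), noise_sd=0.005, seed=21, **cfg_over)
        return gs.preprocess(gs.generate_dataset(cfg))

    def test_training_is_reproducible_under_seed(self):
        ds = self._quick_ds()
        sp = gs.split_dataset(ds, seed=0)
        cfg = TrainConfig(epochs=3, batch_size=16, learning_rate=1e-3, seed=4)
        r1 = train_model(build_cnn(ds.n_bands, seed=4), ds, sp, cfg)
        r2 = train_model(build_cnn(ds.n_bands, seed=4), ds, sp, cfg)
        np.testing.assert_array_equal(r1.loss_history, r2.loss_history)
        np.testing.assert_array_equal(r1.predictions["test"], r2.predictions["test"])

    def test_loss_decreases_on_separable_data(self):
        ds = self._quick_ds()
        sp = gs.split_dataset(ds, seed=0)
        res = train_model(build_cnn(ds.n_bands, seed=0), ds, sp,
                          TrainConfig(epochs=10, batch_size=16, seed=0))
        diffs = np.diff(res.loss_history)
        assert (diffs > 0).sum() <= 2  # allow two upticks over ten epochs

    def test_single_class_task_is_trivially_learned(self):
        cfg = gs.SceneConfig(
            wavelength_grid=np.linspace(476, 890, 16),
            class_counts={"Cabernet": (1, 1, 68, 1)},  # dominated by one class
            noise_sd=0.005, seed=22)
        ds = gs.generate_dataset(cfg)
        one_class = ds.subset(np.flatnonzero(ds.y == 2))
        one_class.y[:] = 0
        n = one_class.n_samples
        sp = gs.SplitIndices(train=np.arange(n - 8), val=np.arange(n - 8, n - 4),
                             test=np.arange(n - 4, n))
        res = train_model(build_cnn(16, seed=0), one_class, sp,
                          TrainConfig(epochs=50, batch_size=16,
                                      learning_rate=3e-3, seed=0))
        assert min(res.loss_history) < 0.01

    def test_initial_loss_near_uniform_entropy(self):
        """Xavier-initialized evaluation-mode logits are near zero, so the
        untrained network's loss on balanced data is ~ln 4."""
        ds = self._quick_ds()
        net = build_cnn(ds.n_bands, seed=0)
        loss, _ = softmax_cross_entropy(net.class_scores(ds.X), ds.y)
        assert loss == pytest.approx(np.log(4), abs=0.3)

    def test_bad_configs_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=-1)
        with pytest.raises(ValueError):
            CnnSpec(dropout=1.5)
        with pytest.raises(ValueError):
            ResNetSpec(block_channels=(256, 128, 64))
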