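"""Autoencoder tests.

The convolution/pool/upsample kernels are checked against independent
oracles (scipy correlation, einsum contractions over explicit sliding
windows); the feature summary and masks against brute-force loops; and
training for seeded reproducibility and loss reduction.
"""

import numpy as np
import pytest
from scipy.signal import correlate

from matriscope.autoencoder import (
    AutoencoderSpec,
    BottleneckActivation,
    build_autoencoder,
    encode,
    feature_matrix,
    make_feature_masks,
    summarize_features,
    train,
    _k_conv,
    _k_conv_dw,
    _k_pool,
    _k_pool_grad,
    _k_upsample,
    _k_upsample_grad,
    _pad_frame,
)
from matriscope.synthetic import generate_image
from matriscope.tiling import tile_image
from tests.conftest import random_rgb

rng = np.random.default_rng(42)


class TestKernelOracles:
    """Stencil kernels vs independent float64 references."""

    def test_conv_matches_scipy_correlate(self):
        x = rng.random((2, 3, 9, 11)).astype(np.float32)
        W = rng.normal(size=(3, 3, 3, 5)).astype(np.float32)
        b = rng.normal(size=5).astype(np.float32)
        y = _k_conv(_pad_frame(x), W, b, False)
        for n in range(2):
            for co in range(5):
                ref = np.full((9, 11), float(b[co]))
                for ci in range(3):
                    ref += correlate(
                        np.pad(x[n, ci].astype(np.float64), 1),
                        W[:, :, ci, co].astype(np.float64),
                        mode="valid",
                    )
                np.testing.assert_allclose(y[n, co], ref, atol=1e-5)

    def test_conv_relu_clamps_negatives(self):
        x = rng.random((1, 2, 6, 6)).astype(np.float32)
        W = rng.normal(size=(3, 3, 2, 4)).astype(np.float32)
        b = np.full(4, -10.0, dtype=np.float32)  # force negative preactivation
        y = _k_conv(_pad_frame(x), W, b, True)
        assert np.all(y == 0.0)

    def test_weight_gradient_matches_einsum(self):
        x = rng.random((2, 3, 8, 10)).astype(np.float32)
        dy = rng.normal(size=(2, 4, 8, 10)).astype(np.float32)
        dW = _k_conv_dw(_pad_frame(x), dy)
        xp = np.pad(x.astype(np.float64), ((0, 0), (0, 0), (1, 1), (1, 1)))
        for u in range(3):
            for v in range(3):
                ref = np.einsum(
                    "ncij,ndij->cd",
                    xp[:, :, u : u + 8, v : v + 10],
                    dy.astype(np.float64),
                )
                np.testing.assert_allclose(dW[u, v], ref, atol=1e-4)

    def test_input_gradient_is_transposed_convolution(self):
        # dL/dx[p] = sum_q dy[q] W[q <- p]; brute-force over all pixels
        x = rng.random((1, 2, 5, 6)).astype(np.float32)
        W = rng.normal(size=(3, 3, 2, 3)).astype(np.float32)
        dy = rng.normal(size=(1, 3, 5, 6)).astype(np.float32)
        Wt = np.ascontiguousarray(W[::-1, ::-1].transpose(0, 1, 3, 2))
        dx = _k_conv(_pad_frame(dy), Wt, np.zeros(2, np.float32), False)
        ref = np.zeros((1, 2, 5, 6))
        for i in range(5):
            for j in range(6):
                for u in range(3):
                    for v in range(3):
                        oi, oj = i - (u - 1), j - (v - 1)
                        if 0 <= oi < 5 and 0 <= oj < 6:
                            for ci in range(2):
                                ref[0, ci, i, j] += (
                                    dy[0, :, oi, oj] @ W[u, v, ci, :]
                                )
        np.testing.assert_allclose(dx, ref, atol=1e-5)

    def test_pool_and_gradient(self):
        x = rng.random((2, 3, 6, 8)).astype(np.float32)
        y = _k_pool(x)
        ref = x.reshape(2, 3, 3, 2, 4, 2).max(axis=(3, 5))
        np.testing.assert_array_equal(y, ref)
        # gradient goes to the argmax only
        dy = rng.normal(size=y.shape).astype(np.float32)
        dx = _k_pool_grad(x, y, dy)
        np.testing.assert_allclose(dx.reshape(2, 3, 3, 2, 4, 2).sum(axis=(3, 5)), dy,
                                   rtol=1e-6)
        assert np.count_nonzero(dx) == dy.size  # no ties in random input

    def test_pool_gradient_splits_ties_evenly(self):
        x = np.full((1, 1, 2, 2), 0.5, dtype=np.float32)
        y = _k_pool(x)
        dx = _k_pool_grad(x, y, np.ones((1, 1, 1, 1), dtype=np.float32))
        np.testing.assert_allclose(dx, 0.25)

    def test_upsample_and_gradient(self):
        x = rng.random((2, 2, 3, 4)).astype(np.float32)
        y = _k_upsample(x)
        np.testing.assert_array_equal(y, x.repeat(2, axis=2).repeat(2, axis=3))
        dy = rng.normal(size=y.shape).astype(np.float32)
        dx = _k_upsample_grad(dy)
        np.testing.assert_allclose(
            dx, dy.reshape(2, 2, 3, 2, 4, 2).sum(axis=(3, 5)), rtol=1e-5
        )


class TestArchitecture:
    def test_bottleneck_shape(self):
        model = build_autoencoder()
        z = model.encode_batch(random_rgb((1, 104, 120, 3)))
        assert z.shape == (1, 13, 15, 16)
        assert np.all(z >= 0)  # rectified bottleneck

    def test_reconstruction_shape_and_range(self):
        model = build_autoencoder()
        y = model.forward(random_rgb((2, 104, 120, 3)))
        assert y.shape == (2, 104, 120, 3)
        assert np.all((y > 0) & (y < 1))

    def test_batch_axis(self):
        model = build_autoencoder()
        z = model.encode_batch(random_rgb((5, 104, 120, 3)))
        assert z.shape == (5, 13, 15, 16)

    def test_layer_counts(self):
        spec = AutoencoderSpec()
        assert spec.n_layers == 9
        assert spec.n_encoder_layers == 5
        assert spec.n_decoder_layers == 4

    def test_inconsistent_spec_rejected(self):
        with pytest.raises(ValueError, match="input dims / 8"):
            AutoencoderSpec(bottleneck_shape=(12, 15, 16)).validate()
        with pytest.raises(ValueError, match="bottleneck channel"):
            AutoencoderSpec(encoder_channels=(8, 16, 16, 16, 8)).validate()

    def test_zero_weights_give_zero_activations(self):
        model = build_autoencoder()
        for layer in model.encoder:
            if layer.params:
                layer.W[:] = 0
                layer.b[:] = 0
        z = model.encode_batch(random_rgb((1, 104, 120, 3)))
        assert np.all(z == 0)

    def test_identical_tiles_identical_activations(self):
        model = build_autoencoder()
        tile = random_rgb((1, 104, 120, 3))
        batch = np.concatenate([tile, tile])
        z = model.encode_batch(batch)
        np.testing.assert_array_equal(z[0], z[1])


class TestTraining:
    @pytest.fixture(scope="class")
    @staticmethod
    def tiny_tiles():
        img = generate_image("network_dense", seed=2)
        ts = tile_image(img, 10, 12)
        return ts.pixel_array()[:32]

    @pytest.fixture(scope="class")
    @staticmethod
    def four_class_tiles():
        from matriscope.synthetic import GeneratorParams, generate_dataset
        from matriscope.tiling import filter_tiles, tile_images

        params = GeneratorParams(height=208, width=240, n_fibers=8, n_steps=80)
        ts = filter_tiles(tile_images(generate_dataset(8, 3, params), 2, 2))
        return ts.pixel_array()[:128]

    def test_loss_history_and_reduction(self, tiny_tiles):
        spec = AutoencoderSpec(epochs=5, batch_size=16, seed=0)
        model = build_autoencoder(spec)
        history = model.fit(tiny_tiles)
        assert len(history) == 5
        assert history[-1] < history[0]

    def test_early_epochs_strictly_reduce_loss(self, four_class_tiles):
        """Loss falls strictly over the first 5 epochs on 4-class tiles."""
        for seed in (0, 1, 2):
            model = build_autoencoder(AutoencoderSpec(epochs=5, seed=seed))
            history = model.fit(four_class_tiles)
            assert all(b < a for a, b in zip(history, history[1:])), history

    def test_training_is_seeded(self, tiny_tiles):
        h1 = build_autoencoder(AutoencoderSpec(epochs=2, seed=3)).fit(tiny_tiles)
        h2 = build_autoencoder(AutoencoderSpec(epochs=2, seed=3)).fit(tiny_tiles)
        assert h1 == h2

    def test_constant_zero_tiles_converge_to_dark_output(self):
        # small frames keep this overfitting check fast
        spec = AutoencoderSpec(
            input_shape=(16, 16, 3),
            bottleneck_shape=(2, 2, 16),
            epochs=450,
            batch_size=4,
            learning_rate=0.05,
            seed=0,
        )
        model = build_autoencoder(spec)
        zeros = np.zeros((4, 16, 16, 3), dtype=np.float32)
        history = model.fit(zeros)
        assert history[-1] < 0.01  # approaching the zero-image entropy (0)
        assert model.forward(zeros).max() <= 0.01

    def test_single_tile_overfit_beats_constant_baseline(self, tiny_tiles):
        tile = tiny_tiles[:1]
        spec = AutoencoderSpec(epochs=40, batch_size=1, learning_rate=5e-3, seed=1)
        model = build_autoencoder(spec)
        model.fit(tile)
        x = tile.astype(np.float64)
        const = np.clip(np.full_like(x, x.mean()), 1e-7, 1 - 1e-7)
        baseline = float(-np.mean(x * np.log(const) + (1 - x) * np.log(1 - const)))
        assert model.reconstruction_loss(tile) < baseline

    def test_empty_training_set_rejected(self):
        model = build_autoencoder()
        with pytest.raises(ValueError, match="non-empty"):
            model.fit(np.zeros((0, 104, 120, 3), dtype=np.float32))

    def test_train_wrapper_returns_history(self, tiny_tiles):
        model = build_autoencoder(AutoencoderSpec(epochs=1, seed=0))
        model, history = train(model, tiny_tiles[:8])
        assert len(history) == 1


class TestFeatures:
    def _activation(self, maps, tile_id="t0"):
        return BottleneckActivation(maps=maps.astype(np.float32), tile_id=tile_id)

    def test_constant_map_mean(self):
        maps = np.zeros((13, 15, 16))
        maps[:, :, 3] = 0.7
        fv = summarize_features(self._activation(maps))
        assert fv.values[3] == pytest.approx(0.7)
        assert len(fv.values) == 16

    def test_matches_bruteforce_mean(self):
        maps = rng.random((13, 15, 16))
        fv = summarize_features(self._activation(maps))
        for k in range(16):
            total = 0.0
            for i in range(13):
                for j in range(15):
                    total += maps[i, j, k]
            assert fv.values[k] == pytest.approx(total / 195, rel=1e-6)

    def test_encode_preserves_order_and_ids(self):
        model = build_autoencoder()
        x = random_rgb((3, 104, 120, 3))
        acts = encode(model, x)
        assert [a.tile_id for a in acts] == ["tile_0", "tile_1", "tile_2"]
        feats, ids = feature_matrix(acts)
        assert feats.shape == (3, 16)

    def test_encode_shape_mismatch_rejected(self):
        model = build_autoencoder()
        with pytest.raises(ValueError, match="does not match"):
            encode(model, random_rgb((1, 64, 64, 3)))


class TestFeatureMasks:
    def _pair(self, maps, tile_id="t0"):
        act = BottleneckActivation(maps=maps.astype(np.float32), tile_id=tile_id)
        return act, summarize_features(act)

    def test_constant_map_mask_all_true(self):
        act, fv = self._pair(np.full((13, 15, 16), 0.4))
        masks = make_feature_masks(act, fv)
        assert masks.masks.all()  # ties (== mean) are kept
        assert masks.masks.shape == (13, 15, 16)

    def test_two_pixel_perturbation(self):
        maps = np.full((13, 15, 16), 0.5)
        maps[0, 0, 2] = 1.5
        maps[0, 1, 2] = -0.5  # mean of map 2 stays exactly 0.5
        act, fv = self._pair(maps)
        masks = make_feature_masks(act, fv)
        m2 = masks.masks[:, :, 2]
        assert not m2[0, 1]
        assert m2.sum() == 13 * 15 - 1
        assert masks.masks[:, :, 3].all()

    def test_mask_uses_supplied_thresholds_not_recomputed(self):
        act, fv = self._pair(rng.random((13, 15, 16)))
        fv.values = np.full(16, 2.0)  # above every activation
        masks = make_feature_masks(act, fv)
        assert not masks.masks.any()

    def test_tile_id_mismatch_rejected(self):
        act, fv = self._pair(rng.random((13, 15, 16)))
        fv.tile_id = "other"
        with pytest.raises(ValueError, match="mismatch"):
            make_feature_masks(act, fv)

    def test_upsampled_masks_at_tile_resolution(self):
        act, fv = self._pair(rng.random((13, 15, 16)))
        up = make_feature_masks(act, fv).upsampled()
        assert up.shape == (104, 120, 16)


def test_checkpoint_round_trip(tmp_path):
    model = build_autoencoder(AutoencoderSpec(seed=5))
    x = random_rgb((2, 104, 120, 3))
    path = tmp_path / "model.npz"
    model.save(path)
    loaded = type(model).load(path)
    np.testing.assert_array_equal(model.encode_batch(x), loaded.encode_batch(x))
    assert loaded.spec.seed == 5
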