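import numpy as np
import pytest
from scipy import ndimage

from foramcurve.errors import EvaluationError, GeometryError, SpecificationError
from foramcurve.metrics import dice
from foramcurve.phantom import desk_population_spec, generate_population
from foramcurve.segnet import (
    TrainConfig,
    extract_patches,
    patch_origins,
    predict,
    train,
    train_replicates,
)
from foramcurve.segnet.layers import (
    SGD,
    Conv3d,
    MaxPool2,
    Upsample2,
    softmax_cross_entropy,
)
from foramcurve.segnet.unet import UNet3D


@pytest.fixture(scope="module")
def population():
    return generate_population(desk_population_spec(seed=5))


@pytest.fixture(scope="module")
def quick_cfg():
    return TrainConfig.desk_scale(
        patch_size_vox=(8, 8, 8), stride_vox=8, steps_per_epoch=4,
        max_epochs=2, patience_epochs=2, seed=0,
    )


@pytest.fixture(scope="module")
def trained_model(population):
    """One converged desk-scale training on separable phantoms."""
    train_p, val_p, _ = population
    cfg = TrainConfig.desk_scale(
        patch_size_vox=(8, 8, 8), stride_vox=8, steps_per_epoch=4,
        max_epochs=120, patience_epochs=20, seed=11,
    )
    return train(train_p, val_p, cfg)


class TestLayers:
    def test_conv3d_matches_scipy_correlate(self, rng):
        conv = Conv3d(2, 3, 3, rng)
        x = rng.normal(size=(2, 1, 6, 6, 6)).astype(np.float32)  # (C, B, D, H, W)
        y = conv.forward(x)
        W = conv.W.reshape(3, 2, 3, 3, 3)
        for o in range(3):
            expected = sum(
                ndimage.correlate(
                    x[c, 0].astype(float), W[o, c].astype(float),
                    mode="constant", cval=0.0,
                )
                for c in range(2)
            ) + conv.b[o]
            np.testing.assert_allclose(y[o, 0], expected, rtol=1e-4, atol=1e-4)

    def test_maxpool_matches_naive(self, rng):
        pool = MaxPool2()
        x = rng.normal(size=(2, 1, 4, 4, 4)).astype(np.float32)
        y = pool.forward(x)
        for i, j, k in np.ndindex(2, 2, 2):
            block = x[:, :, 2 * i : 2 * i + 2, 2 * j : 2 * j + 2, 2 * k : 2 * k + 2]
            np.testing.assert_allclose(y[:, :, i, j, k], block.max(axis=(2, 3, 4)))

    def test_upsample_adjoint_of_block_sum(self, rng):
        up = Upsample2()
        x = rng.normal(size=(1, 1, 2, 2, 2)).astype(np.float32)
        y = up.forward(x)
        assert y.shape == (1, 1, 4, 4, 4)
        dy = rng.normal(size=y.shape).astype(np.float32)
        dx = up.backward(dy)
        # adjoint identity: <up(x), dy> == <x, up^T(dy)>
        assert float((y * dy).sum()) == pytest.approx(float((x * dx).sum()), rel=1e-4)
        np.testing.assert_allclose(
            dx[0, 0, 0, 0, 0], dy[0, 0, :2, :2, :2].sum(), rtol=1e-5
        )

    def test_gradient_check_full_network(self):
        """Directional finite-difference check through the whole U-Net."""
        net = UNet3D(base_channels=2, n_levels=2, seed=1)
        x = np.random.default_rng(0).normal(size=(2, 1, 4, 4, 4)).astype(np.float32)
        y = np.random.default_rng(1).integers(0, 3, size=(2, 4, 4, 4))
        _, d = softmax_cross_entropy(net.forward(x), y)
        net.backward(d)
        g = [gr.copy() for gr in net.grads()]
        gnorm2 = sum(float((gr**2).sum()) for gr in g)
        eps = 1e-2 / np.sqrt(gnorm2)
        for p, gr in zip(net.params(), g):
            p += eps * gr
        lp = softmax_cross_entropy(net.forward(x), y)[0]
        for p, gr in zip(net.params(), g):
            p -= 2 * eps * gr
        lm = softmax_cross_entropy(net.forward(x), y)[0]
        ratio = (lp - lm) / (2 * eps) / gnorm2
        assert ratio == pytest.approx(1.0, abs=0.01)

    def test_weighted_loss_reduces_to_unweighted(self, rng):
        logits = rng.normal(size=(2, 3, 4, 4, 4)).astype(np.float32)
        targets = rng.integers(0, 3, size=(2, 4, 4, 4))
        l0, d0 = softmax_cross_entropy(logits, targets)
        l1, d1 = softmax_cross_entropy(logits, targets, np.ones(3))
        assert l0 == pytest.approx(l1)
        np.testing.assert_allclose(d0, d1, atol=1e-7)

    def test_sgd_nesterov_step(self):
        p = np.array([1.0], dtype=np.float32)
        opt = SGD([p], lr=0.1, momentum=0.9, nesterov=True)
        opt.step([np.array([1.0], dtype=np.float32)])
        # v = -0.1; p += 0.9*v - 0.1*g = 1 - 0.09 - 0.1
        assert p[0] == pytest.approx(0.81)

    def test_sgd_lr_decay(self):
        p = np.zeros(1, dtype=np.float32)
        opt = SGD([p], lr=1.0, momentum=0.0, decay=1.0)
        opt.step([np.ones(1, dtype=np.float32)])
        opt.step([np.ones(1, dtype=np.float32)])
        # steps of size 1/(1+0) then 1/(1+1)
        assert p[0] == pytest.approx(-1.5)


class TestPatches:
    def test_exact_fit_single_patch(self):
        assert patch_origins(64, 64, 32) == [0]

    def test_stride_grid_with_snap(self):
        assert patch_origins(96, 64, 32) == [0, 32]
        assert patch_origins(90, 64, 32) == [0, 26]

    def test_volume_smaller_than_patch(self):
        with pytest.raises(GeometryError):
            patch_origins(32, 64, 32)

    def test_96_cube_patch_count(self, population):
        # origins {0, 32} per axis -> 2^3 = 8 patches
        pair = population[0][0]
        cfg = TrainConfig(
            patch_size_vox=(64, 64, 64), target_scale_vox=(96, 96, 96),
            stride_vox=32, n_levels=2,
        )
        patches = extract_patches(pair, cfg)
        assert len(patches) == 8

    def test_coverage_union_is_full_volume(self, population, quick_cfg):
        pair = population[0][0]
        cfg = TrainConfig.desk_scale(
            patch_size_vox=(8, 8, 8), stride_vox=5, crop_to_foreground=False
        )
        covered = np.zeros(pair.shape, dtype=int)
        p = cfg.patch_size_vox
        n_windows = 0
        for z in patch_origins(pair.shape[0], p[0], cfg.stride_vox):
            for y in patch_origins(pair.shape[1], p[1], cfg.stride_vox):
                for x in patch_origins(pair.shape[2], p[2], cfg.stride_vox):
                    covered[z : z + p[0], y : y + p[1], x : x + p[2]] += 1
                    n_windows += 1
        assert covered.min() >= 1  # every voxel inside at least one window
        assert len(extract_patches(pair, cfg)) == n_windows

    def test_config_validation(self):
        with pytest.raises(SpecificationError):
            TrainConfig(stride_vox=100, patch_size_vox=(64, 64, 64))
        with pytest.raises(SpecificationError):
            TrainConfig(patience_epochs=300, max_epochs=200)
        with pytest.raises(SpecificationError):
            TrainConfig(patch_size_vox=(63, 64, 64))


class TestTraining:
    def test_empty_training_set(self, population, quick_cfg):
        with pytest.raises(SpecificationError):
            train([], population[1], quick_cfg)

    def test_val_without_foreground(self, population, quick_cfg):
        from foramcurve.stackio import VolumePair

        blank = VolumePair(
            "blank", np.zeros((24, 24, 24), np.uint16),
            np.zeros((24, 24, 24), np.uint8), 1.75,
        )
        with pytest.raises(EvaluationError):
            train(population[0][:1], [blank], quick_cfg)

    def test_determinism_same_seed(self, population, quick_cfg):
        a = train(population[0][:1], population[1], quick_cfg)
        b = train(population[0][:1], population[1], quick_cfg)
        assert a.history == b.history
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_history_invariants(self, trained_model):
        m = trained_model
        assert m.best_val_dice == max(m.history)
        assert m.history.index(m.best_val_dice) + 1 == m.best_epoch
        assert len(m.history) <= m.config.max_epochs
        assert len(m.history) <= m.best_epoch + m.config.patience_epochs

    def test_separable_phantoms_beat_090(self, population, trained_model):
        """The trained net must approach a per-voxel intensity classifier."""
        _, _, test_p = population
        pair = test_p[0]
        means = pair.params["phantom"].intensity_means
        stack = np.stack(
            [
                np.abs(pair.grey.astype(float) - means["background"]),
                np.abs(pair.grey.astype(float) - means["wall"]),
                np.abs(pair.grey.astype(float) - means["cavity"]),
            ]
        )
        oracle_dice = dice(stack.argmin(axis=0), pair.labels)
        assert oracle_dice > 0.95  # intensity alone separates the classes
        assert trained_model.best_val_dice >= 0.9

    def test_early_stop_bounded_by_patience(self, population):
        cfg = TrainConfig.desk_scale(
            patch_size_vox=(8, 8, 8), stride_vox=8, steps_per_epoch=2,
            max_epochs=40, patience_epochs=3, seed=2,
        )
        m = train(population[0][:1], population[1], cfg)
        assert len(m.history) <= m.best_epoch + 3


class TestPredict:
    def test_output_shape_and_labels(self, trained_model, population):
        grey = population[2][0].grey
        pred = predict(trained_model, grey)
        assert pred.shape == grey.shape
        assert set(np.unique(pred)) <= {0, 1, 2}

    def test_background_intensity_maps_to_background(self, trained_model, population):
        bg = population[0][0].params["phantom"].intensity_means["background"]
        grey = np.full((24, 24, 24), bg, dtype=np.uint16)
        pred = predict(trained_model, grey)
        assert np.mean(pred == 0) > 0.99

    def test_too_small_grid(self, trained_model):
        with pytest.raises(GeometryError):
            predict(trained_model, np.zeros((4, 4, 4), dtype=np.uint16))

    def test_high_dice_on_test_specimens(self, trained_model, population):
        scores = [
            dice(predict(trained_model, p.grey), p.labels) for p in population[2]
        ]
        assert float(np.mean(scores)) > 0.85


class TestReplicates:
    def test_median_selection(self, population, quick_cfg):
        from dataclasses import replace

        cfg = replace(quick_cfg, n_replicates=3)
        models, median = train_replicates(population[0][:1], population[1], cfg)
        assert len(models) == 3
        dices = sorted(m.best_val_dice for m in models)
        assert median.best_val_dice == dices[1]

    def test_single_replicate_is_median(self, population, quick_cfg):
        from dataclasses import replace

        cfg = replace(quick_cfg, n_replicates=1)
        models, median = train_replicates(population[0][:1], population[1], cfg)
        assert median is models[0]

    def test_replicates_have_distinct_seeds(self, population, quick_cfg):
        from dataclasses import replace

        cfg = replace(quick_cfg, n_replicates=2)
        models, _ = train_replicates(population[0][:1], population[1], cfg)
        assert models[0].config.seed != models[1].config.seed
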