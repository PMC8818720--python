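"""Network architecture, padding, loss, SSIM, augmentation, training loop."""

import numpy as np
import pytest

from wallshear.nn import (
    LossConfig,
    NetConfig,
    SSIMConfig,
    Tensor,
    TrainConfig,
    WSSNet,
    augment,
    composite_loss,
    cosine_annealing_lr,
    periodic_pad,
    predict_flatmap,
    reduced_config,
    ssim,
    train,
)
from wallshear.nn.train import AugmentConfig, TrainingSample
from wallshear.flatmap import Flatmap


@pytest.fixture(scope="module")
def net():
    return WSSNet(reduced_config(seed=0))


class TestPeriodicPad:
    def test_rows_wrap_circumferentially(self, rng):
        patch = rng.normal(size=(48, 48, 3))
        out = periodic_pad(patch, 1)
        assert np.allclose(out[0, 1:-1], patch[-1])
        assert np.allclose(out[-1, 1:-1], patch[0])

    def test_columns_replicate_longitudinal_edges(self, rng):
        patch = rng.normal(size=(48, 48, 3))
        out = periodic_pad(patch, 1)
        assert np.allclose(out[:, 0][1:-1], patch[:, 0])
        assert np.allclose(out[:, -1][1:-1], patch[:, -1])

    def test_constant_patch_stays_constant(self):
        out = periodic_pad(np.full((48, 48, 2), 3.25), 2)
        assert np.all(out == 3.25)


class TestForward:
    def test_output_has_three_channels_and_input_spatial_shape(self, net, rng):
        x = rng.normal(size=(1, 48, 48, 15))
        assert net(Tensor(x)).shape == (1, 48, 48, 3)

    def test_batch_dimension_preserved(self, net, rng):
        x = rng.normal(size=(5, 48, 48, 15))
        assert net(Tensor(x)).shape == (5, 48, 48, 3)

    def test_wrong_channel_count_rejected(self, net, rng):
        with pytest.raises(ValueError, match="expected"):
            net(Tensor(rng.normal(size=(1, 48, 48, 12))))

    def test_forward_is_deterministic_in_eval_mode(self, rng):
        x = rng.normal(size=(2, 48, 48, 15))
        a = WSSNet(reduced_config(seed=4))
        b = WSSNet(reduced_config(seed=4))
        a.eval()
        b.eval()
        assert np.array_equal(a(Tensor(x)).data, b(Tensor(x)).data)

    def test_patch_edge_matches_template_circumference(self):
        with pytest.raises(ValueError, match="circumference"):
            NetConfig(patch=32)


class TestSSIM:
    def test_identical_images_score_exactly_one(self, rng):
        x = rng.random((20, 20)) * 3.0
        assert ssim(x, x, data_range=3.0).data == 1.0

    def test_matches_reference_implementation(self, rng):
        from skimage.metrics import structural_similarity

        x = rng.random((24, 24)) * 2.0
        y = x + rng.normal(0, 0.3, x.shape)
        ref = structural_similarity(
            x, y, win_size=11, data_range=2.0, gaussian_weights=False,
            use_sample_covariance=True,
        )
        assert abs(float(ssim(x, y, data_range=2.0).data) - ref) < 1e-9

    def test_constant_images_reduce_to_luminance_term(self):
        # zero variance: contrast/structure terms drop out, SSIM = l(x,y)
        a, b, L = 1.5, 2.5, 4.0
        x = np.full((15, 15), a)
        y = np.full((15, 15), b)
        c1 = (0.01 * L) ** 2
        expected = (2 * a * b + c1) / (a * a + b * b + c1)
        assert abs(float(ssim(x, y, data_range=L).data) - expected) < 1e-9

    def test_nonpositive_data_range_rejected(self, rng):
        x = rng.random((15, 15))
        with pytest.raises(ValueError, match="positive"):
            ssim(x, x, data_range=0.0)


class TestLoss:
    @pytest.fixture
    def batch(self, rng):
        truth = rng.normal(size=(2, 48, 48, 3))
        mask = rng.random((2, 48, 48)) > 0.2
        return truth, mask

    def test_perfect_prediction_zero_loss_without_decay(self, batch):
        truth, mask = batch
        loss, _ = composite_loss(
            Tensor(truth), truth, mask, [], LossConfig(weight_decay=0.0)
        )
        assert loss.data == 0.0

    def test_perfect_prediction_leaves_exact_l2_term(self, batch, rng):
        truth, mask = batch
        weights = [Tensor(rng.normal(size=(3, 3, 4, 4)), requires_grad=True)]
        cfg = LossConfig(weight_decay=1e-2, batch_size=16)
        loss, _ = composite_loss(Tensor(truth), truth, mask, weights, cfg)
        expected = 1e-2 / (2 * 16) * float((weights[0].data ** 2).sum())
        assert loss.data == expected

    def test_masked_pixel_perturbations_do_not_change_loss(self, batch, rng):
        truth, mask = batch
        pred = truth + rng.normal(0, 0.1, truth.shape)
        base, _ = composite_loss(Tensor(pred), truth, mask, [], LossConfig())
        pert = pred.copy()
        pert[~mask] += 100.0
        again, _ = composite_loss(Tensor(pert), truth, mask, [], LossConfig())
        assert base.data == again.data

    def test_loss_bounded_below_by_l2_term(self, batch, rng):
        truth, mask = batch
        pred = rng.normal(size=truth.shape)
        weights = [Tensor(rng.normal(size=(3, 3, 4, 4)), requires_grad=True)]
        cfg = LossConfig(weight_decay=1e-2, batch_size=16)
        loss, terms = composite_loss(Tensor(pred), truth, mask, weights, cfg)
        assert loss.data >= terms["l2"] >= 0.0

    def test_empty_mask_rejected(self, batch):
        truth, _ = batch
        with pytest.raises(ValueError, match="mask"):
            composite_loss(
                Tensor(truth), truth, np.zeros(truth.shape[:3], bool), [], LossConfig()
            )


class TestAugment:
    @pytest.fixture
    def sample(self, rng):
        return TrainingSample(
            inputs=rng.normal(size=(48, 48, 15)),
            label=rng.normal(size=(48, 48, 3)),
            mask=rng.random((48, 48)) > 0.1,
        )

    def test_rotation_preserves_vector_magnitudes(self, sample, rng):
        cfg = AugmentConfig(rotate=True, translate=False, max_roll=0, noise_prob=0.0)
        out = augment(sample, cfg, rng)
        for sl in (slice(9, 12), slice(12, 15)):
            assert np.allclose(
                np.linalg.norm(out.inputs[..., sl], axis=2),
                np.linalg.norm(sample.inputs[..., sl], axis=2),
            )
        assert np.allclose(
            np.linalg.norm(out.label, axis=2), np.linalg.norm(sample.label, axis=2)
        )

    def test_rotation_keeps_sheet_distances(self, sample, rng):
        cfg = AugmentConfig(rotate=True, translate=True, max_roll=0, noise_prob=0.0)
        out = augment(sample, cfg, rng)
        d_in = np.linalg.norm(sample.inputs[..., 3:6] - sample.inputs[..., 0:3], axis=2)
        d_out = np.linalg.norm(out.inputs[..., 3:6] - out.inputs[..., 0:3], axis=2)
        assert np.allclose(d_in, d_out)

    def test_translation_leaves_velocities_and_label_untouched(self, sample, rng):
        cfg = AugmentConfig(rotate=False, translate=True, max_roll=0, noise_prob=0.0)
        out = augment(sample, cfg, rng)
        assert np.array_equal(out.inputs[..., 9:], sample.inputs[..., 9:])
        assert np.array_equal(out.label, sample.label)

    def test_roll_moves_all_channels_and_mask_together(self, sample, rng):
        cfg = AugmentConfig(rotate=False, translate=False, max_roll=5, noise_prob=0.0)
        out = augment(sample, cfg, rng)
        # find the shift from the mask and undo it everywhere
        for k in range(-5, 6):
            if np.array_equal(np.roll(sample.mask, k, axis=0), out.mask):
                break
        assert np.array_equal(np.roll(sample.inputs, k, axis=0), out.inputs)
        assert np.array_equal(np.roll(sample.label, k, axis=0), out.label)

    def test_noise_only_touches_velocity_channels(self, sample, rng):
        cfg = AugmentConfig(rotate=False, translate=False, max_roll=0, noise_prob=1.0)
        out = augment(sample, cfg, rng)
        assert np.array_equal(out.inputs[..., :9], sample.inputs[..., :9])
        assert not np.array_equal(out.inputs[..., 9:], sample.inputs[..., 9:])


class TestSchedule:
    def test_cosine_annealing_cycle_endpoints(self):
        assert cosine_annealing_lr(0, 10, 1e-4, 1e-7) == pytest.approx(1e-4)
        assert cosine_annealing_lr(10, 10, 1e-4, 1e-7) == pytest.approx(1e-4)
        lr_end = cosine_annealing_lr(9, 10, 1e-4, 1e-7)
        assert 1e-7 <= lr_end < 3e-6


class TestTraining:
    def test_validation_loss_improves_on_synthetic_data(self, trained):
        _, _, _, history = trained
        assert min(history.val_loss) < 0.8 * history.val_loss[0]

    def test_learning_rate_follows_annealing_schedule(self, trained):
        _, cfg, _, history = trained
        assert history.lr[0] == pytest.approx(cfg.lr_max)
        assert min(history.lr) < 0.1 * cfg.lr_max

    def test_same_seed_reproduces_first_epoch_loss(self):
        from wallshear.synthetic import make_dataset

        data = make_dataset(n_geometries=3, seed=11, n_val=1, n_test=1)
        cfg = TrainConfig(
            epochs=1, patch_pool=64, seed=5, lr_max=1e-3,
            sheet_pairs=[(1.0, 2.0)],
            augment=AugmentConfig(rotate=False),
        )
        _, h1 = train(data["train"], None, reduced_config(5), cfg)
        _, h2 = train(data["train"], None, reduced_config(5), cfg)
        assert h1.train_loss[0] == h2.train_loss[0]

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train([], None, reduced_config(0), TrainConfig(epochs=1))


class TestPredictFlatmap:
    @pytest.fixture
    def model(self):
        net = WSSNet(reduced_config(seed=1))
        net.eval()
        return net

    def test_output_covers_full_template(self, model, rng):
        fm = Flatmap(rng.normal(size=(48, 93, 15)), np.ones((48, 93), bool))
        pred = predict_flatmap(model, fm)
        assert pred.values.shape == (48, 93, 3)
        assert np.array_equal(pred.mask, fm.mask)

    def test_constant_input_prediction_independent_of_stride(self, model):
        fm = Flatmap(np.full((48, 93, 15), 0.37), np.ones((48, 93), bool))
        a = predict_flatmap(model, fm, stride=15)
        b = predict_flatmap(model, fm, stride=45)
        assert np.allclose(a.values, b.values, atol=1e-10)

    def test_too_short_flatmap_rejected(self, model, rng):
        fm = Flatmap(rng.normal(size=(48, 40, 15)), np.ones((48, 40), bool))
        with pytest.raises(ValueError, match="patch edge"):
            predict_flatmap(model, fm)
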