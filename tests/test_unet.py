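import numpy as np
import pytest

from hepaseg.phantom import PhantomSpec, generate_phantom
from hepaseg.unet import (
    EmptyDatasetError,
    TrainingConfig,
    UNet,
    UNetConfig,
    binarize,
    build_unet,
    load_model,
    save_model,
    select_training_slices,
    soft_dice_loss,
    train,
    _soft_dice_grad,
)

TINY = UNetConfig(input_size=(32, 32), depth=2, base_filters=4, dropout_rate=0.0)


class TestArchitecture:
    def test_default_audits_to_19_conv_layers(self):
        assert UNetConfig().conv_layer_count == 19
        assert build_unet().conv_layer_count == 19

    def test_output_shape_and_range(self):
        net = UNet(TINY, seed=0)
        x = np.random.default_rng(0).random((2, 32, 32, 1)).astype(np.float32)
        p, _ = net.forward(x)
        assert p.shape == (2, 32, 32, 1)
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ValueError):
            UNetConfig(input_size=(100, 100), depth=4)

    def test_parameter_count_stable_across_builds(self):
        assert UNet(TINY, seed=0).n_parameters == UNet(TINY, seed=99).n_parameters

    def test_inference_is_deterministic(self):
        net = UNet(TINY, seed=1)
        x = np.random.default_rng(1).random((3, 32, 32, 1)).astype(np.float32)
        p1, _ = net.forward(x)
        p2, _ = net.forward(x)
        np.testing.assert_array_equal(p1, p2)
        # identical slices give identical maps
        x2 = np.repeat(x[:1], 3, axis=0)
        p3, _ = net.forward(x2)
        np.testing.assert_array_equal(p3[0], p3[1])


class TestSoftDiceLoss:
    def test_perfect_overlap_is_zero(self):
        t = (np.random.default_rng(0).random((2, 8, 8, 1)) > 0.5).astype(np.float64)
        assert soft_dice_loss(t, t, eps=1e-12) == pytest.approx(0.0, abs=1e-9)

    def test_all_background_prediction_worked_example(self):
        # pred == 0, target has 100 foreground px, eps=1 -> 1 - 1/101
        target = np.zeros((1, 20, 20, 1))
        target[0, :10, :10, 0] = 1.0
        loss = soft_dice_loss(np.zeros_like(target), target, eps=1.0)
        assert loss == pytest.approx(1 - 1 / 101)

    def test_uniform_half_prediction_closed_form(self):
        n = 16 * 16
        target = np.zeros((1, 16, 16, 1))
        target[0, :8, :, 0] = 1.0  # half foreground
        pred = np.full_like(target, 0.5)
        assert soft_dice_loss(pred, target, eps=1e-12) == pytest.approx(0.5)

    def test_loss_in_unit_interval_and_shape_check(self):
        rng = np.random.default_rng(4)
        p = rng.random((3, 8, 8, 1))
        t = (rng.random((3, 8, 8, 1)) > 0.5).astype(float)
        assert 0.0 <= soft_dice_loss(p, t) <= 1.0
        with pytest.raises(ValueError):
            soft_dice_loss(p, t[:2])

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0.05, 0.95, (2, 6, 6, 1))
        t = (rng.random((2, 6, 6, 1)) > 0.5).astype(np.float64)
        g = _soft_dice_grad(p, t, eps=1.0)
        for idx in [(0, 1, 2, 0), (1, 4, 4, 0), (0, 5, 0, 0)]:
            h = 1e-6
            pp = p.copy()
            pp[idx] += h
            num = (soft_dice_loss(pp, t, 1.0) - soft_dice_loss(p, t, 1.0)) / h
            assert g[idx] == pytest.approx(num, rel=1e-3, abs=1e-10)


class TestBackprop:
    def test_network_gradients_match_finite_differences(self):
        cfg = UNetConfig(input_size=(16, 16), depth=2, base_filters=2,
                         dropout_rate=0.0)
        net = UNet(cfg, seed=1)
        for k in net.params:
            net.params[k] = net.params[k].astype(np.float64)
        rng = np.random.default_rng(2)
        x = rng.random((2, 16, 16, 1))
        y = (rng.random((2, 16, 16, 1)) > 0.7).astype(np.float64)
        p, caches = net.forward(x)
        d = _soft_dice_grad(p, y, 1.0).astype(np.float64) * p * (1 - p)
        grads = net.backward(d, caches)
        for name in ["enc0_0_w", "mid_1_w", "up1_w", "dec0_w", "out_w", "up0_b"]:
            w = net.params[name]
            idx = tuple(rng.integers(0, s) for s in w.shape)
            h = 1e-6
            orig = w[idx]
            w[idx] = orig + h
            lp = soft_dice_loss(net.forward(x)[0], y, 1.0)
            w[idx] = orig - h
            lm = soft_dice_loss(net.forward(x)[0], y, 1.0)
            w[idx] = orig
            num = (lp - lm) / (2 * h)
            assert grads[name][idx] == pytest.approx(num, rel=1e-4, abs=1e-9)


@pytest.fixture(scope="module")
def corpus():
    spec = PhantomSpec(shape=(64, 64, 32), tumor_count=2,
                       tumor_radius_range=(4.0, 6.0), seed=21)
    with_tumor = generate_phantom(spec)
    spec0 = PhantomSpec(shape=(64, 64, 32), tumor_count=0, seed=22)
    without = generate_phantom(spec0)
    return with_tumor, without


class TestSliceSelection:
    def test_liver_stage_counts_nonempty_slices(self, corpus):
        (vol, liver, tumor), _ = corpus
        ds = select_training_slices([vol], [liver], [tumor], "liver",
                                    input_size=(64, 64))
        expected = int((liver.voxels.sum(axis=(0, 1)) > 0).sum())
        assert len(ds) == expected
        assert ds.x.shape[1:3] == (64, 64)
        # every target nonempty
        assert (ds.y.reshape(len(ds), -1).sum(axis=1) > 0).all()

    def test_tumor_free_volume_contributes_nothing(self, corpus):
        (vol, liver, tumor), (vol0, liver0, tumor0) = corpus
        ds_both = select_training_slices(
            [vol, vol0], [liver, liver0], [tumor, tumor0], "tumor",
            input_size=(64, 64),
        )
        ds_one = select_training_slices([vol], [liver], [tumor], "tumor",
                                        input_size=(64, 64))
        assert len(ds_both) == len(ds_one)

    def test_all_empty_corpus_raises(self, corpus):
        _, (vol0, liver0, tumor0) = corpus
        with pytest.raises(EmptyDatasetError):
            select_training_slices([vol0], [liver0], [tumor0], "tumor",
                                   input_size=(64, 64))


class TestTraining:
    def test_zero_epochs_is_a_noop(self):
        net = UNet(TINY, seed=0)
        before = {k: v.copy() for k, v in net.params.items()}
        x = np.random.default_rng(0).random((4, 32, 32, 1)).astype(np.float32)
        y = np.zeros_like(x)
        y[:, 10:20, 10:20, :] = 1.0
        from hepaseg.unet import SliceDataset

        _, hist = train(net, SliceDataset(x, y), TrainingConfig(epochs=0))
        assert hist == []
        for k in before:
            np.testing.assert_array_equal(net.params[k], before[k])

    def test_lr_after_two_reductions(self):
        tc = TrainingConfig()
        assert tc.lr0 * tc.lr_factor**2 == pytest.approx(1e-5)

    def test_plateau_schedule_reduces_lr_with_floor(self):
        # min_delta larger than any possible improvement -> every epoch counts
        # as a plateau -> lr falls by lr_factor every patience epochs down to
        # the min_lr floor
        net = UNet(TINY, seed=0)
        x = np.random.default_rng(0).random((4, 32, 32, 1)).astype(np.float32)
        y = np.ones_like(x)
        from hepaseg.unet import SliceDataset

        tc = TrainingConfig(epochs=9, batch_size=4, lr_patience_epochs=2,
                            validation_fraction=0.0, seed=0, min_delta=10.0)
        _, hist = train(net, SliceDataset(x, y), tc)
        lrs = [h["lr"] for h in hist]
        assert lrs[0] == pytest.approx(1e-3)
        assert pytest.approx(1e-4) in lrs  # one reduction by lr_factor
        assert min(lrs) == pytest.approx(1e-5)  # clamped at the floor


class TestPredictBinarize:
    def test_binarize_threshold_and_ties(self):
        maps = np.full((2, 8, 8), 0.6)
        assert binarize(maps).all()
        assert binarize(np.full((8, 8), 0.5)).all()  # ties go to foreground
        assert not binarize(np.full((8, 8), 0.49)).any()
        with pytest.raises(ValueError):
            binarize(maps, threshold=1.5)

    def test_predict_volume_slice_count_and_range(self):
        from hepaseg.unet import predict_volume

        net = UNet(TINY, seed=0)
        vol = np.random.default_rng(0).random((32, 32, 5)).astype(np.float32)
        maps = predict_volume(net, vol)
        assert maps.shape == (5, 32, 32)
        assert maps.min() >= 0 and maps.max() <= 1
        with pytest.raises(ValueError):
            predict_volume(net, np.zeros((16, 16, 3), dtype=np.float32))


def test_checkpoint_round_trip(tmp_path):
    net = UNet(TINY, seed=3)
    p = tmp_path / "model.npz"
    save_model(net, p)
    back = load_model(p)
    assert back.cfg == net.cfg
    x = np.random.default_rng(0).random((1, 32, 32, 1)).astype(np.float32)
    np.testing.assert_array_equal(back.forward(x)[0], net.forward(x)[0])
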