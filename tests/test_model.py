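"""Autoencoder architecture, composite loss, training and ablation tests."""

import numpy as np
import pytest

from fibersr.metrics import global_ssim, ssim
from fibersr.model import (
    ModelSpec,
    TrainingConfig,
    build_model,
    channel_ablation,
    composite_loss,
    load_model,
    restore,
    save_model,
    train,
    _loss_terms_and_grad,
)


def _toy_data(rng, n, c, size):
    x = rng.uniform(0, 1, (n, c, size, size)).astype(np.float32)
    y = rng.uniform(0, 1, (n, 1, size, size)).astype(np.float32)
    return x, y


class TestCompositeLoss:
    def test_identical_images_give_zero(self, rng):
        x = rng.uniform(0, 1, (16, 16))
        assert composite_loss(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_constant_images_closed_form(self):
        # constants differing by d: MAE=d, MSE=d^2, SSIM from zero-variance form
        d = 0.2
        x = np.full((16, 16), 0.5)
        y = np.full((16, 16), 0.5 + d)
        c1 = 0.01**2
        s = (2 * 0.5 * 0.7 + c1) / (0.5**2 + 0.7**2 + c1)
        expected = 0.001 * d + 1.0 * d**2 + 0.001 * (1.0 - s)
        assert composite_loss(x, y) == pytest.approx(expected, abs=1e-12)

    def test_weight_decomposition(self, rng):
        x = rng.uniform(0, 1, (16, 16))
        y = rng.uniform(0, 1, (16, 16))
        only_mae = TrainingConfig(mae_weight=1, mse_weight=0, ssim_weight=0)
        only_mse = TrainingConfig(mae_weight=0, mse_weight=1, ssim_weight=0)
        only_ssim = TrainingConfig(mae_weight=0, mse_weight=0, ssim_weight=1)
        assert composite_loss(x, y, only_mae) == pytest.approx(np.abs(x - y).mean())
        assert composite_loss(x, y, only_mse) == pytest.approx(((x - y) ** 2).mean())
        assert composite_loss(x, y, only_ssim) == pytest.approx(1 - global_ssim(x, y), abs=1e-12)

    def test_default_weights_are_the_published_coefficients(self):
        cfg = TrainingConfig()
        assert (cfg.mae_weight, cfg.mse_weight, cfg.ssim_weight) == (0.001, 1.0, 0.001)
        assert cfg.learning_rate == 1e-4 and cfg.patience_epochs == 5

    def test_literal_ssim_sign_flag(self, rng):
        x = rng.uniform(0, 1, (16, 16))
        literal = TrainingConfig(literal_ssim_sign=True)
        # literal formula adds +w*SSIM instead of +w*(1-SSIM)
        diff = composite_loss(x, x, literal) - composite_loss(x, x)
        assert diff == pytest.approx(0.001 * 1.0, abs=1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        p = rng.uniform(0.2, 0.8, (2, 1, 8, 8))
        t = rng.uniform(0.2, 0.8, (2, 1, 8, 8))
        cfg = TrainingConfig()
        _, g = _loss_terms_and_grad(p, t, cfg)
        eps = 1e-6
        for idx in [(0, 0, 2, 3), (1, 0, 7, 0), (0, 0, 5, 5)]:
            pp, pm = p.copy(), p.copy()
            pp[idx] += eps
            pm[idx] -= eps
            num = (_loss_terms_and_grad(pp, t, cfg)[0] - _loss_terms_and_grad(pm, t, cfg)[0]) / (2 * eps)
            assert g[idx] == pytest.approx(num, rel=1e-5, abs=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            composite_loss(np.zeros((8, 8)), np.zeros((4, 4)))


class TestBuildModel:
    def test_multiframe_spec_maps_11_channels_to_one(self, rng):
        model = build_model(ModelSpec(input_channels=11, encoder_widths=(8, 16)), seed=0)
        x = rng.uniform(0, 1, (1, 11, 32, 32)).astype(np.float32)
        out = model.forward(x)
        assert out.shape == (1, 1, 32, 32)
        assert out.min() >= 0.0 and out.max() <= 1.0  # sigmoid head

    def test_single_image_variant_keeps_stages(self, rng):
        siae = build_model(ModelSpec(input_channels=1, encoder_widths=(8, 16)), seed=0)
        mfae = build_model(ModelSpec(input_channels=11, encoder_widths=(8, 16)), seed=0)
        assert len(siae.net.layers) == len(mfae.net.layers)
        out = siae.forward(rng.uniform(0, 1, (1, 1, 32, 32)).astype(np.float32))
        assert out.shape == (1, 1, 32, 32)

    def test_same_seed_gives_identical_initial_parameters(self):
        a = build_model(ModelSpec(input_channels=3, encoder_widths=(4, 8)), seed=9)
        b = build_model(ModelSpec(input_channels=3, encoder_widths=(4, 8)), seed=9)
        for pa, pb in zip(a.get_state(), b.get_state()):
            assert np.array_equal(pa, pb)

    def test_indivisible_spatial_size_raises(self, rng):
        model = build_model(ModelSpec(input_channels=1, encoder_widths=(4, 8, 8)), seed=0)
        with pytest.raises(ValueError):
            model.forward(rng.uniform(0, 1, (1, 1, 30, 30)).astype(np.float32))

    def test_channel_mismatch_raises(self, rng):
        model = build_model(ModelSpec(input_channels=11, encoder_widths=(4, 8)), seed=0)
        with pytest.raises(ValueError):
            model.forward(rng.uniform(0, 1, (1, 3, 32, 32)).astype(np.float32))


class TestTrain:
    def test_learning_sanity_loss_decreases(self, rng):
        x, y = _toy_data(rng, 20, 3, 16)
        y = x.mean(axis=1, keepdims=True)  # learnable mapping
        data = {"train": (x, y), "val": (x[:4], y[:4])}
        model = build_model(ModelSpec(input_channels=3, encoder_widths=(8, 16)), seed=1)
        cfg = TrainingConfig(max_epochs=15, batch_size=4, learning_rate=1e-3, seed=0)
        model, hist = train(model, data, cfg)
        assert hist.train_loss[-1] < hist.train_loss[0]
        assert hist.epochs_run <= cfg.max_epochs

    def test_flat_validation_stops_after_exactly_patience_epochs(self, rng):
        x, y = _toy_data(rng, 6, 1, 16)
        data = {"train": (x, y), "val": (x, y)}
        model = build_model(ModelSpec(input_channels=1, encoder_widths=(4,)), seed=1)
        # effectively frozen parameters: vanishing learning rate
        cfg = TrainingConfig(max_epochs=50, batch_size=6, learning_rate=1e-30, seed=0)
        model, hist = train(model, data, cfg)
        assert hist.stopped_early
        assert hist.epochs_run == cfg.patience_epochs == 5

    def test_best_validation_parameters_are_retained(self, rng):
        x, y = _toy_data(rng, 12, 1, 16)
        y = 1.0 - x
        data = {"train": (x, y), "val": (x[:3], y[:3])}
        model = build_model(ModelSpec(input_channels=1, encoder_widths=(4, 8)), seed=2)
        cfg = TrainingConfig(max_epochs=10, batch_size=4, learning_rate=1e-3, seed=0)
        model, hist = train(model, data, cfg)
        from fibersr.model import _dataset_loss

        final = _dataset_loss(model, x[:3], y[:3], cfg, 4)
        assert final == pytest.approx(min([hist.val_loss[hist.best_epoch - 1]] if hist.best_epoch else [final]), abs=1e-6)
        assert final <= min(hist.val_loss) + 1e-6

    def test_same_seed_reproduces_loss_curves_exactly(self, rng):
        x, y = _toy_data(rng, 8, 1, 16)
        data = {"train": (x, y), "val": (x[:2], y[:2])}
        hists = []
        for _ in range(2):
            model = build_model(ModelSpec(input_channels=1, encoder_widths=(4, 8)), seed=3)
            _, hist = train(model, data, TrainingConfig(max_epochs=4, batch_size=4, seed=5))
            hists.append(hist)
        assert hists[0].train_loss == hists[1].train_loss
        assert hists[0].val_loss == hists[1].val_loss

    def test_empty_split_raises(self, rng):
        x, y = _toy_data(rng, 4, 1, 16)
        model = build_model(ModelSpec(input_channels=1, encoder_widths=(4,)), seed=0)
        with pytest.raises(ValueError):
            train(model, {"train": (x[:0], y[:0]), "val": (x, y)}, TrainingConfig())


class TestRestore:
    def test_untrained_output_is_shape_valid_in_unit_range(self, fixtures):
        model = build_model(ModelSpec(input_channels=11, encoder_widths=(4, 8)), seed=0)
        out = restore(model, fixtures["stack"])
        assert out.shape == fixtures["stack"].ground_truth.shape
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_trained_model_beats_its_raw_input_frame(self, fixtures):
        # brief training on the packaged stack's tiles should already beat
        # the raw honeycomb frame in SSIM on a held-out tile
        from fibersr.bundle import build_stack

        tiles = [t.image for t in fixtures["tiles"]]
        stacks = np.stack(
            [build_stack(t, fixtures["layout"], masks=fixtures["masks"]).frames for t in tiles]
        )
        gts = np.stack(tiles)[:, None]
        data = {"train": (stacks[:8], gts[:8]), "val": (stacks[8:9], gts[8:9])}
        model = build_model(ModelSpec(input_channels=11, encoder_widths=(8, 16)), seed=4)
        cfg = TrainingConfig(max_epochs=25, batch_size=1, learning_rate=1e-3, seed=0)
        model, _ = train(model, data, cfg)
        held_out = build_stack(tiles[9], fixtures["layout"], masks=fixtures["masks"])
        restored = restore(model, held_out)
        assert ssim(restored, tiles[9]) > ssim(held_out.frame_at(0.0), tiles[9])

    def test_channel_mismatch_raises(self, fixtures):
        model = build_model(ModelSpec(input_channels=3, encoder_widths=(4,)), seed=0)
        with pytest.raises(ValueError):
            restore(model, fixtures["stack"])


class TestChannelAblation:
    def test_eleven_channels_beat_one(self):
        # a small but converged comparison: the multi-frame model overtakes
        # the single-frame variant once training is long enough to exploit
        # the extra rotational coverage
        from fibersr.bundle import StackDataset, build_stack, precompute_masks
        from fibersr.experiments import default_layout, make_phantom_tiles

        layout = default_layout(64, seed=17)
        masks = precompute_masks(layout)
        tiles = [t.image for t in make_phantom_tiles(24, 64, 3, seed=18)]
        stacks = np.stack([build_stack(t, layout, masks=masks).frames for t in tiles])
        gts = np.stack(tiles)
        angles = tuple(float(a) for a in range(-10, 11, 2))
        splits = {
            "train": StackDataset(stacks[:16], gts[:16], angles),
            "val": StackDataset(stacks[16:20], gts[16:20], angles),
            "test": StackDataset(stacks[20:], gts[20:], angles),
        }
        cfg = TrainingConfig(max_epochs=80, batch_size=1, learning_rate=1e-3, seed=0)
        table = channel_ablation(splits, [1, 11], cfg, encoder_widths=(8, 16))
        assert set(table["channels"]) == {1, 11}
        assert "sd_ssim" in table.columns
        by = table.set_index("channels")
        assert by.loc[11, "mean_ssim"] > by.loc[1, "mean_ssim"]

    def test_even_or_oversized_counts_raise(self, fixtures):
        from fibersr.bundle import StackDataset

        splits = {
            "train": StackDataset(
                fixtures["stack"].frames[None], fixtures["stack"].ground_truth[None],
                fixtures["stack"].angles,
            )
        }
        cfg = TrainingConfig(max_epochs=1)
        with pytest.raises(ValueError):
            channel_ablation(splits, [2], cfg)
        with pytest.raises(ValueError):
            channel_ablation(splits, [13], cfg)


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path, rng):
        model = build_model(ModelSpec(input_channels=11, encoder_widths=(4, 8)), seed=7)
        x = rng.uniform(0, 1, (1, 11, 16, 16)).astype(np.float32)
        before = model.forward(x)
        save_model(model, tmp_path / "model.npz")
        loaded = load_model(tmp_path / "model.npz")
        assert np.array_equal(loaded.forward(x), before)
        assert loaded.spec == model.spec
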