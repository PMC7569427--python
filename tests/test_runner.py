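import numpy as np
import pytest

from wanet.metrics import roc_auc
from wanet.model import LasppSpec, NetworkConfig, SegmentationModel, build_wa_net
from wanet.nn import Conv2d
from wanet.preprocess import extract_patches, preprocess_pipeline
from wanet.runner import TrainConfig, init_weights, predict_image, train
from wanet.synthfundus import SynthConfig, generate_dataset


def tiny_config(patch: int = 16) -> NetworkConfig:
    return NetworkConfig(encoder_widths=(2, 4, 8), laspp=LasppSpec(channels=8),
                         patch_size=patch)


class TestInitWeights:
    def test_he_variance_moment(self):
        """A 3x3, 64-channel-in kernel has sample variance ~ 2/fan_in."""
        conv = Conv2d(64, 16, 3, name="c")
        init_weights(conv, seed=0)
        w = conv.effective_weight()
        expected = 2.0 / (3 * 3 * 64)
        assert w.var() == pytest.approx(expected, rel=0.15)
        assert abs(w.mean()) < 0.1 * np.sqrt(expected)

    def test_seed_reproducibility(self):
        m1 = init_weights(build_wa_net(tiny_config(), seed=0), seed=3)
        m2 = init_weights(build_wa_net(tiny_config(), seed=1), seed=3)
        for p1, p2 in zip(m1.params(), m2.params()):
            np.testing.assert_array_equal(p1.val, p2.val)
        m3 = init_weights(build_wa_net(tiny_config(), seed=0), seed=4)
        assert any(not np.array_equal(p1.val, p3.val)
                   for p1, p3 in zip(m1.params(), m3.params()))

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            init_weights(build_wa_net(tiny_config()), scheme="glorot")


class TestTrainMechanics:
    def _data(self, n=40, s=16, seed=0):
        r = np.random.default_rng(seed)
        x = r.random((n, s, s), dtype=np.float32)
        y = (x < 0.3).astype(int)
        return x, y

    def test_val_split_arithmetic(self):
        x, y = self._data(100)
        m = init_weights(build_wa_net(tiny_config(), seed=0), seed=0)
        hist = train(m, x, y, TrainConfig(epochs=1, batch_size=32, seed=0))
        assert hist.n_train == 90 and hist.n_val == 10
        assert len(hist.train_loss) == len(hist.val_loss) == 1

    def test_zero_learning_rate_is_null_update(self):
        x, y = self._data(40)
        m = init_weights(build_wa_net(tiny_config(), seed=0), seed=0)
        before = [p.val.copy() for p in m.params()]
        train(m, x, y, TrainConfig(epochs=1, batch_size=16, lr=0.0, seed=0))
        for p, b in zip(m.params(), before):
            np.testing.assert_array_equal(p.val, b)

    def test_overfit_small_set(self):
        """A tiny model driven long enough on a few patches overfits:
        the loss falls well below its starting value."""
        x, y = self._data(16)
        m = init_weights(build_wa_net(tiny_config(), seed=0), seed=0)
        hist = train(m, x, y, TrainConfig(epochs=60, batch_size=16, seed=0))
        assert hist.train_loss[-1] < 0.5 * hist.train_loss[0]
        assert hist.train_loss[-1] < 0.8

    def test_seeded_training_deterministic(self):
        x, y = self._data(40)
        losses = []
        for _ in range(2):
            m = init_weights(build_wa_net(tiny_config(), seed=0), seed=0)
            hist = train(m, x, y, TrainConfig(epochs=2, batch_size=16, seed=5))
            losses.append(hist.train_loss)
        assert losses[0] == losses[1]

    def test_misaligned_inputs_rejected(self):
        x, y = self._data(10)
        m = build_wa_net(tiny_config())
        with pytest.raises(ValueError):
            train(m, x, y[:5], TrainConfig(epochs=1))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(val_fraction=0)
        with pytest.raises(ValueError):
            TrainConfig(batch_size=0)


@pytest.fixture(scope="module")
def tiny_trained(small_synth_cfg):
    """A small model trained briefly on synthetic patches, with held-out
    matched and mildly shifted test images."""
    train_set = generate_dataset(3, small_synth_cfg, seed=21)
    xs, ys = [], []
    for i, (img, mask, fov) in enumerate(train_set):
        proc = preprocess_pipeline(img)
        gx, gy = extract_patches(proc, mask, size=16, mode="random",
                                 n=120, seed=31 + i, fov=fov)
        xs.append(gx.patches)
        ys.append(gy.patches)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    model = init_weights(build_wa_net(tiny_config(), seed=1), seed=1)
    hist = train(model, x, y, TrainConfig(epochs=10, batch_size=32, seed=1))
    import dataclasses
    shifted_cfg = dataclasses.replace(small_synth_cfg, noise_sd=0.045,
                                      vessel_darkness=0.30)
    matched = generate_dataset(2, small_synth_cfg, seed=900)
    shifted = generate_dataset(2, shifted_cfg, seed=901)
    return model, hist, matched, shifted


def _pooled_auc(model, images):
    ps, ts = [], []
    for img, mask, fov in images:
        pmap = predict_image(model, preprocess_pipeline(img),
                             patch_size=16, stride=8)
        f = fov.astype(bool)
        ps.append(pmap[f])
        ts.append(np.asarray(mask)[f])
    _, auc = roc_auc(np.concatenate(ps), np.concatenate(ts))
    return auc


class TestTrainedModel:
    def test_loss_decreases(self, tiny_trained):
        _, hist, _, _ = tiny_trained
        assert hist.train_loss[-1] < hist.train_loss[0]
        assert hist.best_epoch >= 1

    def test_predict_image_shape_and_range(self, tiny_trained, small_synth_cfg):
        model, _, matched, _ = tiny_trained
        img = preprocess_pipeline(matched[0][0])
        pmap = predict_image(model, img, patch_size=16, stride=8)
        assert pmap.shape == img.shape
        assert pmap.min() >= 0 and pmap.max() <= 1

    def test_stride_equal_to_patch_tiles_without_overlap(self, tiny_trained,
                                                         small_synth_cfg):
        model, _, matched, _ = tiny_trained
        img = preprocess_pipeline(matched[0][0])  # 96x96: exact 16-tiling
        pmap = predict_image(model, img, patch_size=16, stride=16)
        assert pmap.shape == img.shape

    def test_held_out_auc_beats_chance_clearly(self, tiny_trained):
        model, _, matched, _ = tiny_trained
        assert _pooled_auc(model, matched) > 0.7

    def test_mild_domain_shift_small_auc_drop(self, tiny_trained):
        """Evaluating on a mildly shifted synthetic domain (more noise,
        lower vessel contrast) costs little AUC — the scaled-down analogue
        of cross-dataset generalization."""
        model, _, matched, shifted = tiny_trained
        auc_m = _pooled_auc(model, matched)
        auc_s = _pooled_auc(model, shifted)
        assert auc_s > auc_m - 0.1

    def test_checkpoint_round_trip_identical_maps(self, tiny_trained, tmp_path,
                                                  small_synth_cfg):
        model, _, matched, _ = tiny_trained
        img = preprocess_pipeline(matched[1][0])
        ref = predict_image(model, img, patch_size=16, stride=8)
        path = str(tmp_path / "model.npz")
        model.save(path)
        loaded = SegmentationModel.load(path)
        np.testing.assert_array_equal(
            predict_image(loaded, img, patch_size=16, stride=8), ref)


class TestConstantModel:
    def test_zeroed_head_predicts_half_everywhere(self, rng):
        model = build_wa_net(tiny_config(), seed=0)
        model.head.set_weight(np.zeros_like(model.head.effective_weight()))
        model.head.b.val[:] = 0
        img = rng.random((48, 48))
        pmap = predict_image(model, img, patch_size=16, stride=8)
        np.testing.assert_allclose(pmap, 0.5, atol=1e-6)
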