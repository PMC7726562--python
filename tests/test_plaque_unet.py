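"""2D plaque model: augmentation properties, training contracts, inference."""

import numpy as np
import pandas as pd
import pytest

from athero3d import nn
from athero3d.imgio import VolumeStack
from athero3d.plaque_unet import (AugmentSpec, DatasetSplit, UNetSpec2D, augment,
                                  dice_coefficient, evaluate_dice, fine_tune,
                                  load_model, predict_stack, save_model,
                                  subsample_study, train)
from athero3d.preprocess import PreprocSpec2D


@pytest.fixture
def blob_pair():
    """A centered soft blob with its mask."""
    yy, xx = np.mgrid[:64, :64] - 31.5
    img = np.exp(-(yy**2 + xx**2) / 200.0)
    mask = (img > 0.5).astype(np.uint8)
    return img, mask


class TestAugment:
    def test_zero_probability_is_identity(self, blob_pair):
        img, mask = blob_pair
        out_i, out_m = augment(img, mask, AugmentSpec(prob=0.0),
                               np.random.default_rng(0))
        assert np.array_equal(out_i, img) and np.array_equal(out_m, mask)

    def test_flip_twice_is_identity(self, blob_pair):
        img, mask = blob_pair
        spec = AugmentSpec(prob=1.0, rotation_deg=0, zoom_range=(1, 1), skew_deg=0,
                           distortion_sd=0.0)
        # same rng stream draws the same flip axis twice only if re-seeded
        out_i, out_m = augment(img, mask, spec, np.random.default_rng(3))
        back_i, back_m = augment(out_i, out_m, spec, np.random.default_rng(3))
        assert np.allclose(back_m, mask)

    def test_mask_stays_binary_and_aligned(self, blob_pair):
        img, mask = blob_pair
        rng = np.random.default_rng(7)
        for _ in range(20):
            out_i, out_m = augment(img, mask, AugmentSpec(), rng)
            assert set(np.unique(out_m)) <= {0, 1}
            assert out_i.shape == img.shape and out_m.shape == mask.shape

    def test_foreground_count_stable_over_draws(self, blob_pair):
        """Default magnitudes keep the blob's mask area within 50% over
        many seeded draws (geometry is perturbed, not destroyed)."""
        img, mask = blob_pair
        rng = np.random.default_rng(11)
        base = int(mask.sum())
        for _ in range(100):
            _, out_m = augment(img, mask, AugmentSpec(), rng)
            assert abs(int(out_m.sum()) - base) < 0.5 * base

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match="prob"):
            AugmentSpec(prob=1.5)


def _tiny_pairs(n=8, size=16, seed=0):
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n):
        img = rng.random((size, size))
        mask = (img > 0.7).astype(np.uint8)
        pairs.append((img, mask))
    return pairs


class TestTraining:
    def test_same_seed_same_history(self):
        pairs = _tiny_pairs()
        split = DatasetSplit(train=pairs[:6], validation=pairs[6:])
        net = UNetSpec2D(depth=1, base_filters=4, input_size=(16, 16),
                         max_epochs=4, patience=10, seed=5)
        h1 = train(split, net).history
        h2 = train(split, net).history
        pd.testing.assert_frame_equal(h1, h2)

    def test_empty_split_rejected(self):
        net = UNetSpec2D(depth=1, base_filters=4, input_size=(16, 16))
        with pytest.raises(ValueError, match="non-empty"):
            train(DatasetSplit(train=[], validation=_tiny_pairs(2)), net)

    def test_input_size_must_match_depth(self):
        with pytest.raises(ValueError, match="divisible"):
            UNetSpec2D(depth=4, input_size=(72, 72))

    def test_fine_tune_zero_epochs_is_identity(self):
        pairs = _tiny_pairs()
        net = UNetSpec2D(depth=1, base_filters=4, input_size=(16, 16),
                         max_epochs=2, seed=1)
        split = DatasetSplit(train=pairs[:6], validation=pairs[6:])
        res = train(split, net)
        tuned = fine_tune(res.model, split, net, epochs=0)
        for a, b in zip(res.model.get_weights(), tuned.model.get_weights()):
            assert np.array_equal(a, b)

    def test_fine_tune_does_not_mutate_original(self):
        pairs = _tiny_pairs()
        net = UNetSpec2D(depth=1, base_filters=4, input_size=(16, 16),
                         max_epochs=2, seed=1)
        split = DatasetSplit(train=pairs[:6], validation=pairs[6:])
        res = train(split, net)
        before = res.model.get_weights()
        fine_tune(res.model, split, net, epochs=2)
        for a, b in zip(before, res.model.get_weights()):
            assert np.array_equal(a, b)

    def test_subsample_study_row_count_and_pool_check(self):
        pairs = _tiny_pairs(n=12)
        net = UNetSpec2D(depth=1, base_filters=2, input_size=(16, 16),
                         max_epochs=1, seed=0)
        split = DatasetSplit(train=pairs[:8], validation=pairs[8:10])
        model = train(split, net).model
        table = subsample_study(model, pairs[:10], pairs[10:], net,
                                sizes=(2, 4), repeats=2, epochs=1, seed=0)
        assert len(table) == 4
        assert set(table["size"]) == {2, 4}
        with pytest.raises(ValueError, match="pool"):
            subsample_study(model, pairs[:3], pairs[10:], net, sizes=(5,), repeats=1)


class TestPredictStack:
    @pytest.fixture(scope="class")
    def tiny_model(self):
        return nn.UNet(ndim=2, depth=1, base_filters=2, seed=0)

    def test_output_dims_match_input(self, tiny_model):
        rng = np.random.default_rng(0)
        stack = VolumeStack(voxels=rng.integers(0, 65536, (6, 40, 40)).astype(np.uint16),
                            spacing=(8, 4.8, 4.8))
        out = predict_stack(tiny_model, stack, PreprocSpec2D(target_size=(32, 32)))
        assert out.shape == stack.shape
        assert set(np.unique(out)) <= {0, 1}

    def test_threshold_above_one_gives_empty(self, tiny_model):
        rng = np.random.default_rng(1)
        stack = VolumeStack(voxels=rng.integers(0, 65536, (4, 32, 32)).astype(np.uint16),
                            spacing=(8, 4.8, 4.8))
        out = predict_stack(tiny_model, stack, PreprocSpec2D(target_size=(32, 32)),
                            threshold=1.0 + 1e-9)
        assert out.sum() == 0


def test_checkpoint_round_trip(tmp_path):
    model = nn.UNet(ndim=2, depth=1, base_filters=4, seed=2)
    path = save_model(model, UNetSpec2D(depth=1, base_filters=4, input_size=(16, 16)),
                      tmp_path / "model.npz")
    back = load_model(path)
    x = np.random.default_rng(0).random((1, 16, 16, 1)).astype(np.float32)
    assert np.array_equal(model.predict(x), back.predict(x))
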