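"""3D anatomy net: rotation augmentation, decoding, evaluation metrics."""

import numpy as np
import pytest

from athero3d import nn
from athero3d.anatomy_unet import (CrossValPlan, Sample3D,
                                   make_leave_two_out_plan, one_hot,
                                   per_compartment_dice, predict_anatomy,
                                   rotation_augment, train_anatomy,
                                   upscale_and_postprocess)
from athero3d.imgio import LabelVolume


@pytest.fixture
def volume_label_pair():
    rng = np.random.default_rng(0)
    v = (rng.random((8, 8, 8)) > 0.5).astype(np.uint8)
    l = rng.integers(0, 6, size=(8, 8, 8))
    return v, l


class TestRotationAugment:
    def test_four_n_outputs(self, volume_label_pair):
        v, l = volume_label_pair
        vs, ls = rotation_augment([v, v, v], [l, l, l])
        assert len(vs) == 12 and len(ls) == 12

    def test_class_voxel_counts_preserved(self, volume_label_pair):
        v, l = volume_label_pair
        vs, ls = rotation_augment([v], [l])
        base = {c: (l == c).sum() for c in range(6)}
        for lr in ls:
            assert {c: (lr == c).sum() for c in range(6)} == base

    def test_four_rotations_about_one_axis_identity(self, volume_label_pair):
        v, _ = volume_label_pair
        out = v
        for _ in range(4):
            out = np.rot90(out, k=1, axes=(1, 2))
        assert np.array_equal(out, v)

    def test_volume_and_labels_rotate_together(self, volume_label_pair):
        v, l = volume_label_pair
        vs, ls = rotation_augment([v], [l])
        for vr, lr in zip(vs, ls):
            # foreground structure of labels follows the volume rotation
            assert vr.shape == lr.shape

    def test_misaligned_inputs_rejected(self, volume_label_pair):
        v, l = volume_label_pair
        with pytest.raises(ValueError, match="aligned"):
            rotation_augment([v, v], [l])


class TestPredictAnatomy:
    def test_one_hot_channels_return_that_class(self):
        model = nn.UNet(ndim=3, out_channels=6, depth=1, base_filters=2, seed=0)
        rng = np.random.default_rng(1)
        lab = rng.integers(0, 6, size=(8, 8, 8))

        class Stub:
            def predict(self, x):
                return one_hot(lab)[None]

        out = predict_anatomy(Stub(), np.ones((8, 8, 8), dtype=np.uint8))
        assert np.array_equal(out, lab)

    def test_tie_breaks_to_lowest_class(self):
        class Stub:
            def predict(self, x):
                return np.full((1, 4, 4, 4, 6), 1.0 / 6)

        out = predict_anatomy(Stub(), np.ones((4, 4, 4), dtype=np.uint8))
        assert np.all(out == 0)

    def test_wrong_dims_rejected(self):
        model = nn.UNet(ndim=3, out_channels=6, depth=1, base_filters=2, seed=0)
        with pytest.raises(ValueError, match="3D"):
            predict_anatomy(model, np.ones((4, 4)))


class TestPerCompartmentDice:
    def test_identical_labels_all_one(self, small_phantom):
        spec, af, cd, truth = small_phantom
        d = per_compartment_dice(truth.anatomy_labels, truth.anatomy_labels)
        assert all(d[k] == 1.0 for k in ("DESC", "ARCH", "BCA", "LSA", "LCCA", "mean"))

    def test_swapped_classes_reflect_overlap_only(self):
        """8^3 case enumerated by hand: swapping DESC and ARCH zeroes their
        dice (disjoint regions) while the other classes stay 1 (absent)."""
        lab = np.zeros((8, 8, 8), dtype=np.int64)
        lab[:4] = 1   # DESC
        lab[4:] = 2   # ARCH
        swapped = np.where(lab == 1, 2, np.where(lab == 2, 1, 0))
        d = per_compartment_dice(LabelVolume(labels=swapped, spacing=(1, 1, 1)),
                                 LabelVolume(labels=lab, spacing=(1, 1, 1)))
        assert d["DESC"] == 0.0 and d["ARCH"] == 0.0
        assert d["BCA"] == d["LSA"] == d["LCCA"] == 1.0
        assert d["mean"] == pytest.approx(3 / 5)

    def test_disjoint_class_scores_zero(self):
        a = np.zeros((4, 4, 4), dtype=np.int64)
        b = np.zeros((4, 4, 4), dtype=np.int64)
        a[0, 0, 0] = 3
        b[3, 3, 3] = 3
        d = per_compartment_dice(LabelVolume(labels=a, spacing=(1, 1, 1)),
                                 LabelVolume(labels=b, spacing=(1, 1, 1)))
        assert d["BCA"] == 0.0

    def test_dims_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            per_compartment_dice(LabelVolume(labels=np.zeros((4, 4, 4), dtype=np.int64),
                                             spacing=(1, 1, 1)),
                                 LabelVolume(labels=np.zeros((5, 5, 5), dtype=np.int64),
                                             spacing=(1, 1, 1)))


class TestUpscaleAndPostprocess:
    def test_roundtrip_keeps_high_dice(self, small_phantom):
        spec, af, cd, truth = small_phantom
        from athero3d.preprocess import resize_volume

        small = resize_volume(truth.anatomy_labels.labels, (16, 16, 16), kind="labels")
        pred = upscale_and_postprocess(small, truth.aorta_mask, spec.spacing)
        d = per_compartment_dice(pred, truth.anatomy_labels)
        assert d["mean"] >= 0.9

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            upscale_and_postprocess(np.ones((8, 8, 8), dtype=np.int64),
                                    np.zeros((16, 16, 16)), (1, 1, 1))

    def test_output_classes_subset_of_input(self, small_phantom):
        spec, af, cd, truth = small_phantom
        small = np.zeros((16, 16, 16), dtype=np.int64)
        small[4:12, 4:12, 4:12] = 2
        pred = upscale_and_postprocess(small, truth.aorta_mask, spec.spacing)
        assert set(np.unique(pred.labels)) <= {0, 2}


class TestCrossValidation:
    def test_plan_holds_out_one_per_group(self):
        samples = [Sample3D(sample_id=f"s{i}", binary=np.zeros((4, 4, 4)),
                            labels=np.zeros((4, 4, 4), dtype=np.int64),
                            group="A" if i % 2 == 0 else "B") for i in range(8)]
        plan = make_leave_two_out_plan(samples, n_folds=4, seed=0)
        groups = {s.sample_id: s.group for s in samples}
        for held in plan.folds:
            assert len(held) == 2
            assert {groups[h] for h in held} == {"A", "B"}

    def test_unknown_held_out_id_rejected(self):
        plan = CrossValPlan(folds=[("nope",)])
        with pytest.raises(ValueError, match="unknown"):
            plan.validate(["a", "b"])

    def test_training_loss_matches_eval_dice_family(self):
        """The training metric (1 - smoothed mean compartment dice) agrees
        with the unsmoothed evaluation dice on a perfect prediction."""
        rng = np.random.default_rng(0)
        lab = rng.integers(0, 6, size=(1, 8, 8, 8))
        onehot = one_hot(lab)[None][0][None]
        logits = (one_hot(lab)[None][0][None] * 2 - 1) * 40.0
        loss, _ = nn.dice_multiclass_loss(logits, onehot)
        assert loss == pytest.approx(0.0, abs=0.01)


class TestHeavyCrossVal:
    """Leave-two-out phantom cross-validation (shared session fixture)."""

    def test_mean_compartment_dice(self, anatomy_cv_results):
        assert anatomy_cv_results["mean_dice"] >= 0.75

    def test_four_folds_two_held_out_each(self, anatomy_cv_results):
        assert len(anatomy_cv_results["folds"]) == 4
        assert len(anatomy_cv_results["report"]) == 8

    def test_no_fold_leakage(self, anatomy_cv_results):
        for fold in anatomy_cv_results["folds"]:
            assert len(set(fold.held_out)) == 2
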