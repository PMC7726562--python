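"""3D U-net anatomy labelling: the registration-free alternative.

A small volumetric U-net maps the binarized, downsampled aorta (one input
channel) to six class-probability channels — the five labelled compartments
of the aortic tree plus the unlabelled remainder.  The training loss is
1 minus the mean smoothed dice over the five labelled compartments (the
unlabelled class is excluded from the average but still competes through
the softmax).  The dataset is augmented with the three single-axis 90°
rotations of every sample, evaluation follows a leave-two-out
cross-validation plan (one held-out sample per cohort tag per fold), and
predictions are scored after nearest-neighbour upscaling and the same
label post-processing used by the atlas route.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .atlas_reg import postprocess_labels
from .imgio import COMPARTMENTS, CLASS_IDS, LabelVolume
from .preprocess import resize_volume

N_CLASSES = 6


@dataclass
class UNetSpec3D:
    """Architecture and training hyperparameters for the anatomy model."""

    input_size: tuple[int, int, int] = (64, 64, 64)
    depth: int = 2
    base_filters: int = 4
    lr: float = 1e-5
    max_epochs: int = 300
    patience: int = 15
    batch_size: int = 2
    val_fraction: float = 0.10
    norm: str = "instance"    # per-sample feature normalization in each block
    #: supervise the unlabelled channel too; without it the background is an
    #: unconstrained degree of freedom for the argmax decode (see methods note)
    loss_includes_background: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError(f"lr must be > 0, got {self.lr}")
        if any(s % 2 ** self.depth for s in self.input_size):
            raise ValueError(
                f"input_size {self.input_size} must be divisible by 2^depth={2**self.depth}")


@dataclass
class Sample3D:
    """One training sample: binary input volume, label volume, identity."""

    sample_id: str
    binary: np.ndarray       # (D, H, W) {0,1} at network size
    labels: np.ndarray       # (D, H, W) int in 0..5 at network size
    group: str = ""          # cohort tag (e.g. genotype) used by the CV plan


@dataclass
class CrossValPlan:
    """Leave-two-out folds: per fold the held-out sample ids (one per group)."""

    folds: list = field(default_factory=list)   # list of tuples of held-out ids

    def validate(self, sample_ids):
        ids = set(sample_ids)
        for k, held in enumerate(self.folds):
            missing = set(held) - ids
            if missing:
                raise ValueError(f"fold {k} holds out unknown samples {sorted(missing)}")


def make_leave_two_out_plan(samples: list, n_folds: int = 4, seed: int = 0) -> CrossValPlan:
    """Build a plan holding out one sample per cohort group in each fold."""
    rng = np.random.default_rng(seed)
    groups: dict[str, list] = {}
    for s in samples:
        groups.setdefault(s.group, []).append(s.sample_id)
    folds = []
    pools = {g: list(rng.permutation(ids)) for g, ids in groups.items()}
    for k in range(n_folds):
        held = tuple(pools[g][k % len(pools[g])] for g in sorted(pools))
        folds.append(held)
    return CrossValPlan(folds=folds)


def rotation_augment(volumes: list, labels: list) -> tuple[list, list]:
    """Add the three single-axis 90° rotations of every sample (4n total).

    The identical rotation hits volume and labels, so per-class voxel counts
    are preserved exactly.
    """
    if len(volumes) != len(labels):
        raise ValueError("volumes and labels must be aligned")
    out_v, out_l = [], []
    for v, l in zip(volumes, labels):
        out_v.append(v)
        out_l.append(l)
        for axes in ((1, 2), (0, 2), (0, 1)):   # about z, y, x
            out_v.append(np.rot90(v, k=1, axes=axes).copy())
            out_l.append(np.rot90(l, k=1, axes=axes).copy())
    return out_v, out_l


def one_hot(labels: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    return np.eye(n_classes, dtype=np.float32)[np.asarray(labels, dtype=np.int64)]


@dataclass
class FoldResult:
    fold: int
    held_out: tuple
    model: nn.UNet
    history: pd.DataFrame
    report: pd.DataFrame   # per held-out sample: per-compartment dice + mean


def train_anatomy(samples: list, plan: CrossValPlan, net: UNetSpec3D,
                  eval_truth: dict | None = None) -> list:
    """Train one network per fold of the leave-two-out plan.

    ``eval_truth`` optionally maps sample_id to
    ``(truth LabelVolume, aorta_mask, spacing)`` at evaluation resolution;
    when given, each fold's held-out samples are scored after
    upscale-and-postprocess.  Fold leakage (a held-out id in the training
    set) is impossible by construction and asserted anyway.
    """
    plan.validate([s.sample_id for s in samples])
    by_id = {s.sample_id: s for s in samples}
    results = []
    for k, held in enumerate(plan.folds):
        train_samples = [s for s in samples if s.sample_id not in held]
        if any(s.sample_id in held for s in train_samples):
            raise RuntimeError(f"fold {k} leakage: held-out ids present in training set")
        vols, labs = rotation_augment([s.binary for s in train_samples],
                                      [s.labels for s in train_samples])
        X = np.asarray(vols, dtype=np.float32)[..., None]
        Y = np.stack([one_hot(l) for l in labs])
        rng = np.random.default_rng(net.seed + k)
        n_val = max(1, int(np.ceil(net.val_fraction * len(X))))
        order = rng.permutation(len(X))
        val_idx, train_idx = order[:n_val], order[n_val:]
        model = nn.UNet(ndim=3, in_channels=1, out_channels=N_CLASSES,
                        depth=net.depth, base_filters=net.base_filters,
                        seed=net.seed + k, norm=net.norm)
        Xv, Yv = X[val_idx], Y[val_idx]
        class_idx = (0, 1, 2, 3, 4, 5) if net.loss_includes_background else (1, 2, 3, 4, 5)

        def loss_fn(logits, onehot, class_idx=class_idx):
            return nn.dice_multiclass_loss(logits, onehot, class_idx=class_idx)

        def val_fn(m, Xv=Xv, Yv=Yv):
            scores = []
            for i in range(0, len(Xv), 4):
                logits = m.forward(Xv[i:i + 4], train=False)
                loss, _ = loss_fn(logits, Yv[i:i + 4])
                scores.append(1.0 - loss)
            return float(np.mean(scores))

        res = nn.train_loop(model, loss_fn, (X[train_idx], Y[train_idx]),
                            val_fn, lr=net.lr, max_epochs=net.max_epochs,
                            patience=net.patience, batch_size=net.batch_size,
                            seed=net.seed + 100 + k)
        report_rows = []
        if eval_truth is not None:
            for sid in held:
                truth_lab, aorta_mask, _sp = eval_truth[sid]
                pred64 = predict_anatomy(res.model, by_id[sid].binary)
                pred = upscale_and_postprocess(pred64, aorta_mask, truth_lab.spacing)
                dice = per_compartment_dice(pred, truth_lab)
                dice.update({"sample_id": sid, "fold": k})
                report_rows.append(dice)
        results.append(FoldResult(fold=k, held_out=held, model=res.model,
                                  history=res.history, report=pd.DataFrame(report_rows)))
    return results


def predict_anatomy(model: nn.UNet, binary: np.ndarray) -> np.ndarray:
    """Per-voxel argmax over the six class channels (ties -> lowest class)."""
    binary = np.asarray(binary)
    if binary.ndim != 3:
        raise ValueError(f"expected a 3D binary volume, got ndim={binary.ndim}")
    probs = model.predict(binary[None, ..., None].astype(np.float32))[0]
    return np.argmax(probs, axis=-1).astype(np.int64)


def upscale_and_postprocess(labels_small: np.ndarray, aorta_mask: np.ndarray,
                            spacing) -> LabelVolume:
    """Nearest-neighbour upscale to the aorta-mask grid, then enforce exact
    coverage of the mask (hole filling, outside removal, nearest-class fill)."""
    aorta_mask = np.asarray(aorta_mask)
    if not (aorta_mask > 0).any():
        raise ValueError("aorta mask is empty")
    up = resize_volume(np.asarray(labels_small), aorta_mask.shape, kind="labels")
    return postprocess_labels(LabelVolume(labels=up.astype(np.int64), spacing=spacing),
                              aorta_mask)


def per_compartment_dice(pred: LabelVolume, truth: LabelVolume) -> dict:
    """Plain (unsmoothed) dice per labelled compartment plus their mean.

    A class absent from both volumes scores 1 by convention (nothing to get
    wrong).  Returns {'DESC': ..., ..., 'mean': ...}.
    """
    p, t = pred.labels, truth.labels
    if p.shape != t.shape:
        raise ValueError(f"dims mismatch: {p.shape} vs {t.shape}")
    out = {}
    for name in COMPARTMENTS:
        c = CLASS_IDS[name]
        pc, tc = p == c, t == c
        denom = pc.sum() + tc.sum()
        out[name] = float(2.0 * (pc & tc).sum() / denom) if denom else 1.0
    out["mean"] = float(np.mean([out[n] for n in COMPARTMENTS]))
    return out
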