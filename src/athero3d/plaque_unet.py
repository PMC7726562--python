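"""2D U-net plaque segmentation on autofluorescence cross-sections.

The model is trained with the smoothed dice loss

    d = (2*XY + 1) / (X + Y + 1),      loss = 1 - d,

where ``XY`` is the sum of elementwise products of the predicted probability
map and the binary target, and ``X``, ``Y`` are the sums of each map.  The
+1 smoothing makes the loss well-defined (and equal to 1) on slices without
plaque.  Optimisation uses Adam at learning rate 1e-4 with early stopping on
validation dice; augmentation applies skews, rotations, flips, zoom and
random elastic distortions, each independently with 30% probability, with
the identical geometric transform applied to image and mask.

Fine-tuning re-trains all weights (none frozen) at the same learning rate on
data from a new acquisition mode, and :func:`subsample_study` measures how
many annotated images such an adaptation needs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import nn
from .imgio import VolumeStack
from .preprocess import PreprocSpec2D, preprocess_slice, resize_volume


@dataclass
class UNetSpec2D:
    """Architecture and training hyperparameters for the plaque model."""

    depth: int = 4
    base_filters: int = 16
    input_size: tuple[int, int] = (480, 608)   # (height, width)
    lr: float = 1e-4
    max_epochs: int = 500
    fine_tune_epochs: int = 300
    patience: int = 25
    batch_size: int = 4
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError(f"lr must be > 0, got {self.lr}")
        if self.depth < 1:
            raise ValueError(f"depth must be >= 1, got {self.depth}")
        if any(s % 2 ** self.depth for s in self.input_size):
            raise ValueError(
                f"input_size {self.input_size} must be divisible by 2^depth={2**self.depth}")


@dataclass
class AugmentSpec:
    """Augmentation operations, each drawn independently per sample."""

    prob: float = 0.3
    rotation_deg: float = 20.0
    zoom_range: tuple[float, float] = (0.9, 1.1)
    skew_deg: float = 10.0
    distortion_sd: float = 2.0       # pixels of elastic displacement
    distortion_smooth: float = 8.0   # gaussian smoothing of the field

    def __post_init__(self):
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError(f"prob must be in [0, 1], got {self.prob}")


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test lists of (image, mask) pairs, images
    already preprocessed to the network input size, masks binary."""

    train: list
    validation: list
    test: list = field(default_factory=list)


def dice_coefficient(pred: np.ndarray, target: np.ndarray, smooth: float = 1.0) -> float:
    """Smoothed dice d = (2*XY + s)/(X + Y + s); equals 1 for identical masks
    and for two empty masks."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    num = 2.0 * (pred * target).sum() + smooth
    den = pred.sum() + target.sum() + smooth
    return float(num / den)


# ---------------------------------------------------------------------------
# augmentation

def _affine_2d(rng, spec: AugmentSpec):
    """Compose flip / rotation / zoom / skew draws into one 2x2 matrix."""
    m = np.eye(2)
    applied = False
    if rng.random() < spec.prob:       # flip (random axis)
        ax = rng.integers(0, 2)
        f = np.eye(2)
        f[ax, ax] = -1.0
        m = f @ m
        applied = True
    if rng.random() < spec.prob:       # rotation
        a = np.deg2rad(rng.uniform(-spec.rotation_deg, spec.rotation_deg))
        m = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]]) @ m
        applied = True
    if rng.random() < spec.prob:       # zoom
        z = rng.uniform(*spec.zoom_range)
        m = m / z
        applied = True
    if rng.random() < spec.prob:       # skew
        s = np.tan(np.deg2rad(rng.uniform(-spec.skew_deg, spec.skew_deg)))
        sk = np.eye(2)
        sk[0, 1] = s
        m = sk @ m
        applied = True
    return m, applied


def augment(image: np.ndarray, mask: np.ndarray, spec: AugmentSpec,
            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Apply one augmentation draw to an aligned (image, mask) pair.

    The same geometric transform hits both; the image is interpolated
    bilinearly, the mask with nearest-neighbour and re-binarised.
    """
    image = np.asarray(image, dtype=np.float64)
    mask = (np.asarray(mask) > 0).astype(np.float64)
    m, applied = _affine_2d(rng, spec)
    elastic = rng.random() < spec.prob
    if not applied and not elastic:
        return image, mask.astype(np.uint8)
    h, w = image.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    out_img, out_msk = image, mask
    if applied:
        offset = center - m @ center
        out_img = ndimage.affine_transform(out_img, m, offset=offset, order=1, mode="constant")
        out_msk = ndimage.affine_transform(out_msk, m, offset=offset, order=0, mode="constant")
    if elastic:
        dz = ndimage.gaussian_filter(rng.normal(0, spec.distortion_sd, (h, w)),
                                     spec.distortion_smooth) * spec.distortion_smooth
        dx = ndimage.gaussian_filter(rng.normal(0, spec.distortion_sd, (h, w)),
                                     spec.distortion_smooth) * spec.distortion_smooth
        rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        coords = np.stack([rr + dz, cc + dx])
        out_img = ndimage.map_coordinates(out_img, coords, order=1, mode="constant")
        out_msk = ndimage.map_coordinates(out_msk, coords, order=0, mode="constant")
    return out_img, (out_msk > 0.5).astype(np.uint8)


# ---------------------------------------------------------------------------
# training

def _to_arrays(pairs) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([np.asarray(im, dtype=np.float32) for im, _ in pairs])[..., None]
    Y = np.stack([(np.asarray(mk) > 0).astype(np.float32) for _, mk in pairs])[..., None]
    return X, Y


def evaluate_dice(model: nn.UNet, pairs, threshold: float | None = None) -> float:
    """Mean smoothed dice of the model over (image, mask) pairs; soft
    probabilities by default, binarised if a threshold is given."""
    if not pairs:
        raise ValueError("cannot evaluate on an empty set")
    X, Y = _to_arrays(pairs)
    scores = []
    for i in range(0, len(X), 8):
        p = model.predict(X[i:i + 8])
        if threshold is not None:
            p = (p >= threshold).astype(np.float64)
        for pj, yj in zip(p, Y[i:i + 8]):
            scores.append(dice_coefficient(pj[..., 0], yj[..., 0]))
    return float(np.mean(scores))


def train(split: DatasetSplit, net: UNetSpec2D, aug: AugmentSpec | None = None,
          max_epochs: int | None = None) -> nn.TrainResult:
    """Train a 2D plaque U-net from scratch on a DatasetSplit.

    Augmentation (when given) is pre-drawn per epoch cycle from a seeded rng;
    early stopping monitors mean validation dice.
    """
    if not split.train or not split.validation:
        raise ValueError("train and validation sets must be non-empty")
    model = nn.UNet(ndim=2, in_channels=1, out_channels=1,
                    depth=net.depth, base_filters=net.base_filters, seed=net.seed)
    return _fit(model, split, net, aug, max_epochs or net.max_epochs, seed=net.seed)


def _fit(model, split, net, aug, max_epochs, seed) -> nn.TrainResult:
    rng = np.random.default_rng(seed + 1)
    base_pairs = list(split.train)

    if aug is not None:
        def make_epoch_data():
            return _to_arrays([augment(im, mk, aug, rng) for im, mk in base_pairs])
    else:
        Xc, Yc = _to_arrays(base_pairs)

        def make_epoch_data():
            return Xc, Yc

    # run the generic loop epoch-by-epoch so augmentation can be redrawn
    val_pairs = split.validation

    def val_fn(m):
        return evaluate_dice(m, val_pairs)

    opt = nn.Adam(model.parameters(), lr=net.lr)
    order_rng = np.random.default_rng(seed + 2)
    best = val_fn(model)
    best_w = model.get_weights()
    best_epoch, bad = 0, 0
    rows = []
    for epoch in range(1, max_epochs + 1):
        X, Y = make_epoch_data()
        order = order_rng.permutation(len(X))
        losses = []
        for s in range(0, len(X), net.batch_size):
            sel = order[s:s + net.batch_size]
            logits = model.forward(X[sel], train=True)
            loss, dlogits = nn.dice_binary_loss(logits, Y[sel])
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            model.backward(dlogits)
            opt.step(model.gradients())
            losses.append(loss)
        val = val_fn(model)
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                     "val_metric": float(val)})
        if val > best + 1e-9:
            best, best_epoch, bad = val, epoch, 0
            best_w = model.get_weights()
        else:
            bad += 1
            if bad > net.patience:
                break
    model.set_weights(best_w)
    return nn.TrainResult(model=model, history=pd.DataFrame(rows),
                          best_epoch=best_epoch, best_val=float(best))


def fine_tune(model: nn.UNet, new_split: DatasetSplit, net: UNetSpec2D,
              aug: AugmentSpec | None = None, epochs: int | None = None) -> nn.TrainResult:
    """Adapt a trained model to a new acquisition mode.

    All weights stay trainable; same dice loss and Adam at the training
    learning rate.  ``epochs=0`` returns an untouched copy.
    """
    model = model.clone()
    epochs = net.fine_tune_epochs if epochs is None else epochs
    if epochs == 0:
        return nn.TrainResult(model=model, history=pd.DataFrame(), best_epoch=0,
                              best_val=float("nan"))
    if not new_split.train or not new_split.validation:
        raise ValueError("train and validation sets must be non-empty")
    return _fit(model, new_split, net, aug, epochs, seed=net.seed + 10_000)


def subsample_study(model: nn.UNet, pool: list, test_pairs: list, net: UNetSpec2D,
                    val_pairs: list | None = None, sizes=(25, 50, 100), repeats: int = 3,
                    epochs: int | None = None, seed: int = 0) -> pd.DataFrame:
    """How many annotated images does fine-tuning need?

    For each subset size, draws ``repeats`` independent seeded samples from
    the fine-tuning pool, fine-tunes a copy of ``model`` on each and scores
    it on the common test set.  Returns a tidy table
    (size, repeat, test_dice).
    """
    if max(sizes) > len(pool):
        raise ValueError(f"pool has {len(pool)} images, need >= {max(sizes)}")
    rows = []
    for size in sizes:
        for rep in range(repeats):
            rng = np.random.default_rng(seed + 1000 * size + rep)
            idx = rng.choice(len(pool), size=size, replace=False)
            sub = [pool[i] for i in idx]
            val = val_pairs if val_pairs is not None else sub[: max(1, size // 5)]
            res = fine_tune(model, DatasetSplit(train=sub, validation=val),
                            net, epochs=epochs)
            rows.append({"size": size, "repeat": rep,
                         "test_dice": evaluate_dice(res.model, test_pairs,
                                                    threshold=net.threshold)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# inference

def predict_stack(model: nn.UNet, stack: VolumeStack, pre: PreprocSpec2D,
                  threshold: float = 0.5) -> np.ndarray:
    """Segment plaque in every slice of a stack.

    Each z-slice is preprocessed, pushed through the model, thresholded, and
    the binary prediction resized back to the native slice dims (nearest
    neighbour).  Returns a binary volume aligned with ``stack``.
    """
    out = np.zeros(stack.shape, dtype=np.uint8)
    z, h, w = stack.shape
    batch, imgs = 8, []
    for i in range(z):
        imgs.append(preprocess_slice(stack.voxels[i], pre)[..., None])
    imgs = np.asarray(imgs, dtype=np.float32)
    for s in range(0, z, batch):
        probs = model.predict(imgs[s:s + batch])[..., 0]
        binm = (probs >= threshold).astype(np.uint8)
        for j, bm in enumerate(binm):
            if bm.shape != (h, w):
                bm = resize_volume(bm[None], (1, h, w), kind="mask")[0]
            out[s + j] = bm
    return out


# ---------------------------------------------------------------------------
# checkpoints

def save_model(model: nn.UNet, net: UNetSpec2D | None, path) -> Path:
    """Write weights (npz) plus a JSON sidecar describing the architecture."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, *model.get_weights())
    meta = {"arch": model.spec_dict()}
    if net is not None:
        meta["train_spec"] = asdict(net)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    return path


def load_model(path) -> nn.UNet:
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    model = nn.UNet(**meta["arch"])
    data = np.load(path if path.suffix == ".npz" else str(path) + ".npz")
    model.set_weights([data[k] for k in data.files])
    return model
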