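"""2D and 3D preprocessing for plaque segmentation and anatomy labelling.

2D route (per optical cross-section): resize to the network input size and
normalise with adaptive histogram equalization (CLAHE), yielding floats in
``[0, 1]``.

3D route (per whole-aorta stack): binarize the autofluorescence volume,
fill the lumen to obtain a solid shape, encode it by the Euclidean distance
(µm) to the nearest background voxel, and resample to the registration or
network grid.  The distance encoding turns the thin vessel wall into a
smooth shape surrogate with useful gradients everywhere inside the aorta,
which is what drives the intensity-based registration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure, filters, transform

from .imgio import VolumeStack


@dataclass
class PreprocSpec2D:
    """2D preprocessing parameters.

    ``target_size`` is (width, height) in pixels; the default matches the
    acquisition-scale slice size used for full-resolution work.  CLAHE
    parameters are exposed because the equalization is part of the model's
    input contract and must match between training and fine-tuning.
    """

    target_size: tuple[int, int] = (608, 480)
    clip_limit: float = 0.01
    tile_grid: tuple[int, int] = (8, 8)

    def __post_init__(self):
        if any(t <= 0 for t in self.target_size):
            raise ValueError(f"target_size must be positive, got {self.target_size}")


@dataclass
class PreprocSpec3D:
    """3D preprocessing parameters: registration grid, network grid and
    binarization method (``"otsu"`` or ``"fixed:<threshold>"``)."""

    registration_size: tuple[int, int, int] = (300, 260, 190)
    network_size: tuple[int, int, int] = (64, 64, 64)
    binarization: str = "otsu"

    def __post_init__(self):
        for name in ("registration_size", "network_size"):
            if any(t <= 0 for t in getattr(self, name)):
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")


def preprocess_slice(image: np.ndarray, spec: PreprocSpec2D | None = None) -> np.ndarray:
    """Resize a single-channel 2D image to ``target_size`` and apply CLAHE.

    Returns a float64 image in ``[0, 1]`` of shape (height, width).
    A constant input stays constant (no contrast to equalize).
    """
    spec = spec or PreprocSpec2D()
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2D single-channel image, got ndim={image.ndim}")
    w, h = spec.target_size
    img = image.astype(np.float64)
    lo, hi = img.min(), img.max()
    if hi > lo:
        img = (img - lo) / (hi - lo)
    else:
        # a flat image carries no contrast to equalize: normalised to zero,
        # which also makes the operation idempotent on constants
        return np.zeros((h, w))
    img = transform.resize(img, (h, w), order=1, anti_aliasing=img.shape[0] > h,
                           preserve_range=True)
    kernel = (max(1, h // spec.tile_grid[1]), max(1, w // spec.tile_grid[0]))
    out = exposure.equalize_adapthist(np.clip(img, 0, 1), kernel_size=kernel,
                                      clip_limit=spec.clip_limit)
    return np.clip(out, 0.0, 1.0)


def binarize_volume(stack: VolumeStack | np.ndarray, method: str = "otsu") -> np.ndarray:
    """Binarize an intensity volume into aorta foreground.

    ``method`` is ``"otsu"`` or ``"fixed:<t>"`` (foreground strictly above t).
    """
    vox = stack.voxels if isinstance(stack, VolumeStack) else np.asarray(stack)
    if vox.size == 0:
        raise ValueError("cannot binarize an empty volume")
    if method == "otsu":
        t = filters.threshold_otsu(vox)
    elif method.startswith("fixed:"):
        t = float(method.split(":", 1)[1])
    else:
        raise ValueError(f"unknown binarization method {method!r}; use 'otsu' or 'fixed:<t>'")
    return (vox > t).astype(np.uint8)


def fill_binary(mask: np.ndarray) -> np.ndarray:
    """Fill enclosed cavities (the lumen) of a binary volume.

    Output is a superset of the input; exterior background is unchanged.
    """
    mask = np.asarray(mask) > 0
    return ndimage.binary_fill_holes(mask).astype(np.uint8)


def distance_encode(filled: np.ndarray, spacing) -> np.ndarray:
    """Encode each foreground voxel by its Euclidean distance (µm) to the
    nearest background voxel; background voxels carry 0.

    Distances are physical (spacing-aware) so that samples acquired at
    different voxel sizes are comparable.
    """
    filled = np.asarray(filled) > 0
    spacing = tuple(float(s) for s in spacing)
    if not filled.any():
        return np.zeros(filled.shape, dtype=np.float32)
    return ndimage.distance_transform_edt(filled, sampling=spacing).astype(np.float32)


def resize_volume(volume: np.ndarray, target_shape, kind: str = "intensity") -> np.ndarray:
    """Resample a volume to ``target_shape`` (Z, Y, X).

    ``kind="intensity"`` uses trilinear interpolation with anti-aliasing on
    downscale; ``kind="labels"`` (or ``"mask"``) uses nearest-neighbour so no
    classes are invented.
    """
    volume = np.asarray(volume)
    target_shape = tuple(int(t) for t in target_shape)
    if any(t <= 0 for t in target_shape):
        raise ValueError(f"target dims must be positive, got {target_shape}")
    if volume.shape == target_shape:
        return volume.copy()
    if kind == "intensity":
        return transform.resize(
            volume.astype(np.float64), target_shape, order=1,
            anti_aliasing=any(t < s for t, s in zip(target_shape, volume.shape)),
            preserve_range=True,
        )
    if kind in ("labels", "mask"):
        out = transform.resize(volume, target_shape, order=0, anti_aliasing=False,
                               preserve_range=True)
        return out.astype(volume.dtype)
    raise ValueError(f"kind must be 'intensity' or 'labels', got {kind!r}")


def prepare_for_registration(stack: VolumeStack, spec: PreprocSpec3D | None = None
                             ) -> tuple[np.ndarray, np.ndarray, tuple[float, float, float]]:
    """Full 3D preprocessing chain for anatomy labelling.

    Binarize -> fill lumen -> resample to the registration grid -> distance
    encode.  Returns ``(distance_volume, binary_mask, spacing_at_grid)`` where
    spacing is rescaled so physical extent is preserved.
    """
    spec = spec or PreprocSpec3D()
    binary = binarize_volume(stack, spec.binarization)
    filled = fill_binary(binary)
    target = spec.registration_size
    resized = resize_volume(filled, target, kind="mask")
    new_spacing = tuple(s * d / t for s, d, t in zip(stack.spacing, stack.shape, target))
    dist = distance_encode(resized, new_spacing)
    return dist, resized.astype(np.uint8), new_spacing
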