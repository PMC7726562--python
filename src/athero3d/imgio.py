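"""Image stack I/O with mandatory physical-spacing metadata.

All volumes are stored in ``(Z, Y, X)`` axis order, intensities with 16-bit
semantics.  Voxel spacing (µm per axis) is never guessed: it travels in a
YAML sidecar next to every TIFF and a missing sidecar is an error, because
the headline outputs of the pipeline are volumes in mm³ and a silent unit
error is the single worst failure mode.

Masks are kept ``{0, 1}`` (uint8) in memory and written as ``{0, 255}``
8-bit TIFF for viewer compatibility.  Anatomy label volumes use the fixed
6-class map below.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

#: Anatomy class map: the five labelled compartments of the aortic tree plus
#: the unlabelled remainder (class 0).
CLASS_MAP = {0: "OTHER", 1: "DESC", 2: "ARCH", 3: "BCA", 4: "LSA", 5: "LCCA"}
CLASS_IDS = {v: k for k, v in CLASS_MAP.items()}
#: The five labelled compartments (excludes OTHER/0).
COMPARTMENTS = ("DESC", "ARCH", "BCA", "LSA", "LCCA")

CHANNELS = ("autofluorescence", "cd45")


class SpacingError(ValueError):
    """Raised when voxel spacing metadata is missing or invalid."""


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise SpacingError(f"spacing must be 3 positive values (z, y, x) in µm, got {spacing}")
    return spacing


@dataclass
class VolumeStack:
    """A 3D intensity volume with physical voxel spacing.

    Parameters
    ----------
    voxels : ndarray, shape (Z, Y, X)
        Intensity volume with 16-bit semantics (values in ``[0, 65535]``).
    spacing : (float, float, float)
        Voxel spacing in µm, ``(z, y, x)`` order.
    channel : str
        One of ``"autofluorescence"`` or ``"cd45"``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    channel: str = "autofluorescence"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D (Z, Y, X), got ndim={self.voxels.ndim}")
        if any(d < 1 for d in self.voxels.shape):
            raise ValueError(f"all dims must be >= 1, got {self.voxels.shape}")
        self.spacing = _check_spacing(self.spacing)
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        vmin, vmax = self.voxels.min(), self.voxels.max()
        if vmin < 0 or vmax > 65535:
            raise ValueError(f"intensities must lie in [0, 65535], got [{vmin}, {vmax}]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class LabelVolume:
    """An integer anatomy-label volume over the 6-class map."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    class_map: dict = field(default_factory=lambda: dict(CLASS_MAP))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3D (Z, Y, X), got ndim={self.labels.ndim}")
        self.spacing = _check_spacing(self.spacing)
        bad = set(np.unique(self.labels)) - set(self.class_map)
        if bad:
            raise ValueError(f"label values outside class map {sorted(self.class_map)}: {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


# ---------------------------------------------------------------------------
# sidecar metadata

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml") if path.suffix else path.with_suffix(".yaml")


def write_sidecar(path, spacing, channel: str | None = None) -> Path:
    meta = {"spacing_um": [float(s) for s in spacing]}
    if channel is not None:
        meta["channel"] = channel
    sc = _sidecar_path(Path(path))
    with open(sc, "w") as fh:
        yaml.safe_dump(meta, fh)
    return sc


def read_sidecar(path) -> dict:
    sc = _sidecar_path(Path(path))
    if not sc.exists():
        raise SpacingError(
            f"no spacing sidecar found at {sc}; voxel spacing is mandatory metadata "
            "(pass spacing explicitly to override)"
        )
    with open(sc) as fh:
        meta = yaml.safe_load(fh)
    if not isinstance(meta, dict) or "spacing_um" not in meta:
        raise SpacingError(f"sidecar {sc} lacks required key 'spacing_um'")
    return meta


# ---------------------------------------------------------------------------
# stacks

def _read_pages(path: Path) -> np.ndarray:
    """Read a multi-page TIFF, or a directory of single-page TIFFs sorted
    lexicographically into Z."""
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise FileNotFoundError(f"no TIFF pages found in directory {path}")
        pages = [tifffile.imread(os.fspath(f)) for f in files]
        shapes = {p.shape for p in pages}
        if len(shapes) > 1:
            raise ValueError(f"mixed page dimensions in {path}: {sorted(shapes)}")
        return np.stack(pages, axis=0)
    arr = tifffile.imread(os.fspath(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected a 2D/3D TIFF at {path}, got ndim={arr.ndim}")
    return arr


def read_stack(path, spacing=None, channel: str | None = None) -> VolumeStack:
    """Read a VolumeStack from a multi-page TIFF or a page directory.

    Spacing is taken from the YAML sidecar unless overridden by the
    ``spacing`` argument; with neither available, an error is raised.
    """
    path = Path(path)
    voxels = _read_pages(path)
    if spacing is None:
        meta = read_sidecar(path)
        spacing = meta["spacing_um"]
        channel = channel or meta.get("channel")
    return VolumeStack(voxels=voxels, spacing=spacing, channel=channel or "autofluorescence")


def write_stack(stack: VolumeStack, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(os.fspath(path), stack.voxels.astype(np.uint16))
    write_sidecar(path, stack.spacing, stack.channel)
    return path


# ---------------------------------------------------------------------------
# masks and label volumes

def write_mask(mask: np.ndarray, spacing, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = (np.asarray(mask) > 0).astype(np.uint8) * 255
    tifffile.imwrite(os.fspath(path), out, photometric="minisblack")
    write_sidecar(path, spacing)
    return path


def read_mask(path, spacing=None) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a binary mask; any value > 0 is foreground, returned as {0, 1}."""
    path = Path(path)
    arr = _read_pages(path) if path.is_dir() or path.suffix else _read_pages(path)
    if spacing is None:
        spacing = read_sidecar(path)["spacing_um"]
    return (arr > 0).astype(np.uint8), _check_spacing(spacing)


def write_labels(labels: LabelVolume, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(os.fspath(path), labels.labels.astype(np.uint8),
                     photometric="minisblack")
    write_sidecar(path, labels.spacing)
    return path


def read_labels(path, spacing=None) -> LabelVolume:
    path = Path(path)
    arr = _read_pages(path)
    if spacing is None:
        spacing = read_sidecar(path)["spacing_um"]
    return LabelVolume(labels=arr.astype(np.int64), spacing=spacing)
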