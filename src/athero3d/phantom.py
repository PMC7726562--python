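"""Synthetic light-sheet aorta phantoms.

The generator sweeps a tube along a parametric centerline — a straight
descending aorta, a half-torus arch and three straight branches (BCA, LCCA,
LSA) leaving the upper arch, plus a short unlabelled ascending stub — and
renders a hollow bright wall around a darker lumen on a 16-bit intensity
grid with anisotropic voxel spacing.  Atherosclerotic plaques are placed as
wall-attached ellipsoids with their own autofluorescence contrast, and a
CD45 channel marks immune-cell infiltration: small plaques are stained
throughout while large plaques are stained only in a peripheral rim,
emulating the restriction of leukocytes to the periphery as plaques mature
and develop acellular cores.

Every phantom ships with exact ground truth (plaque mask, anatomy labels,
CD45 mask, per-object volume table), so the whole pipeline is testable
without any microscopy data.  Output is bit-identical for equal specs
(including the seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .imgio import CLASS_IDS, CLASS_MAP, LabelVolume, VolumeStack

DEFAULT_INTENSITIES = {
    "background": 1000.0,
    "lumen": 4000.0,
    "wall": 20000.0,
    "plaque": 32000.0,
    "cd45": 28000.0,
}

#: Default chance of placing a plaque in each compartment; weighted toward
#: the arch and brachiocephalic artery where murine plaque burden is highest.
DEFAULT_PLAQUE_WEIGHTS = {"ARCH": 0.35, "BCA": 0.30, "DESC": 0.15, "LCCA": 0.10, "LSA": 0.10}


class PhantomSpecError(ValueError):
    """A phantom spec violated an invariant; the message names the field."""


@dataclass
class PhantomSpec:
    """Parameters of one synthetic aorta.

    Geometry is expressed in µm on a (Z, Y, X) voxel grid; z increases from
    the branch tips toward the distal descending aorta.  Defaults give a
    desk-scale phantom (~0.3 Mvoxel) at the anisotropic spacing typical of
    light-sheet z-stacks (8 µm steps, ~4.8 µm in-plane).
    """

    shape: tuple[int, int, int] = (64, 72, 72)
    spacing: tuple[float, float, float] = (8.0, 4.8, 4.8)
    aorta_radius_um: float = 40.0
    wall_fraction: float = 0.55          # lumen radius / outer radius
    arch_curvature: float = 1.0          # scales the arch (half-torus) radius
    branch_radius_um: float = 20.0
    n_plaques: int = 6
    plaque_radius_range_um: tuple[float, float] = (12.0, 40.0)
    plaque_wall_attachment: bool = True
    plaque_compartment_weights: dict = field(default_factory=lambda: dict(DEFAULT_PLAQUE_WEIGHTS))
    cd45_mode: str = "peripheral-rim"    # or "full-infiltration"
    rim_thickness_um: float = 12.0
    rim_radius_cutoff_um: float = 25.0   # equivalent-sphere radius above which only the rim stains
    intensity_levels: dict = field(default_factory=lambda: dict(DEFAULT_INTENSITIES))
    noise_sd: float = 600.0
    seed: int = 0

    def validate(self) -> "PhantomSpec":
        if len(self.shape) != 3 or any(s < 16 for s in self.shape):
            raise PhantomSpecError(f"shape: all dims must be >= 16, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise PhantomSpecError(f"spacing: all values must be > 0, got {self.spacing}")
        if self.aorta_radius_um <= 0:
            raise PhantomSpecError(f"aorta_radius_um: must be > 0, got {self.aorta_radius_um}")
        if not 0 < self.wall_fraction < 1:
            raise PhantomSpecError(f"wall_fraction: must be in (0, 1), got {self.wall_fraction}")
        if self.n_plaques < 0:
            raise PhantomSpecError(f"n_plaques: must be >= 0, got {self.n_plaques}")
        rmin, rmax = self.plaque_radius_range_um
        if rmin > rmax or rmin < max(self.spacing):
            raise PhantomSpecError(
                "plaque_radius_range_um: radii must be >= 1 voxel in every axis "
                f"(>= {max(self.spacing)} µm) and min <= max, got {self.plaque_radius_range_um}"
            )
        if self.cd45_mode not in ("peripheral-rim", "full-infiltration"):
            raise PhantomSpecError(f"cd45_mode: unknown mode {self.cd45_mode!r}")
        for name, level in self.intensity_levels.items():
            if not 0 <= level <= 65535:
                raise PhantomSpecError(f"intensity_levels[{name!r}]: must be in [0, 65535], got {level}")
        if self.noise_sd < 0:
            raise PhantomSpecError(f"noise_sd: must be >= 0, got {self.noise_sd}")
        return self


@dataclass
class PhantomTruth:
    """Exact ground truth accompanying a generated phantom."""

    plaque_mask: np.ndarray          # uint8 {0,1}
    anatomy_labels: LabelVolume      # classes over the filled aorta
    cd45_mask: np.ndarray            # uint8 {0,1}, subset of plaque_mask
    per_object_table: pd.DataFrame   # object_id, voxel_count, volume_mm3, compartment
    aorta_mask: np.ndarray           # filled aorta (wall + lumen + plaque)
    wall_mask: np.ndarray
    lumen_mask: np.ndarray
    object_map: np.ndarray           # int map, 0 background, i = plaque object i


def _centerline(spec: PhantomSpec):
    """Sample the aortic centerline; returns (points, class_id, radius) per segment."""
    ez, ey, ex = (d * s for d, s in zip(spec.shape, spec.spacing))
    y_mid = ey / 2.0
    xc, zc = ex / 2.0, 0.42 * ez
    arch_r = spec.arch_curvature * min(0.28 * ex, 0.22 * ez)
    step = min(spec.spacing) / 2.0
    segs = []

    def line(p0, p1, cls, radius):
        p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
        n = max(2, int(np.linalg.norm(p1 - p0) / step) + 1)
        t = np.linspace(0.0, 1.0, n)[:, None]
        segs.append((p0[None] * (1 - t) + p1[None] * t, cls, radius))

    # arch: half-torus in the X-Z plane, apex toward low z
    theta = np.linspace(0.0, math.pi, max(8, int(math.pi * arch_r / step)))
    arch = np.stack([zc - arch_r * np.sin(theta),
                     np.full_like(theta, y_mid),
                     xc - arch_r * np.cos(theta)], axis=1)
    segs.append((arch, CLASS_IDS["ARCH"], spec.aorta_radius_um))
    # descending aorta from the distal arch end
    line((zc, y_mid, xc + arch_r), (0.92 * ez, y_mid, xc + arch_r),
         CLASS_IDS["DESC"], spec.aorta_radius_um)
    # short unlabelled ascending stub from the proximal arch end
    line((zc, y_mid, xc - arch_r), (zc + 0.18 * ez, y_mid, xc - arch_r),
         CLASS_IDS["OTHER"], spec.aorta_radius_um)
    # three branches leave the upper arch: BCA (proximal), LCCA, LSA (distal);
    # origins span the upper arch as in the mouse, where the BCA and LSA roots
    # sit roughly an arch radius apart
    for cls_name, th_deg in (("BCA", 45.0), ("LCCA", 90.0), ("LSA", 135.0)):
        th = math.radians(th_deg)
        attach = np.array([zc - arch_r * math.sin(th), y_mid, xc - arch_r * math.cos(th)])
        drift = (th_deg - 90.0) / 90.0 * 0.30 * ex
        line(attach, (0.06 * ez, y_mid, attach[2] + drift),
             CLASS_IDS[cls_name], spec.branch_radius_um)
    return segs


def _voxel_coords(spec: PhantomSpec) -> np.ndarray:
    axes = [np.arange(d) * s for d, s in zip(spec.shape, spec.spacing)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    return np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)


def generate_phantom(spec: PhantomSpec) -> tuple[VolumeStack, VolumeStack, PhantomTruth]:
    """Render one phantom; returns (autofluorescence, cd45, truth)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    segs = _centerline(spec)
    coords = _voxel_coords(spec)

    # group segments by tube radius so the inside test uses the right radius
    groups: dict[float, list] = {}
    for pts, cls, radius in segs:
        groups.setdefault(radius, []).append((pts, cls))
    dist_norm = np.full(coords.shape[0], np.inf)
    dist_abs = np.full(coords.shape[0], np.inf)
    nearest_cls = np.zeros(coords.shape[0], dtype=np.int64)
    group_radius = np.zeros(coords.shape[0])
    for radius, entries in groups.items():
        pts = np.concatenate([p for p, _ in entries], axis=0)
        cls = np.concatenate([np.full(len(p), c) for p, c in entries])
        d, idx = cKDTree(pts).query(coords, k=1)
        better = d / radius < dist_norm
        dist_norm[better] = d[better] / radius
        dist_abs[better] = d[better]
        nearest_cls[better] = cls[idx[better]]
        group_radius[better] = radius

    inside = dist_norm <= 1.0
    lumen = dist_norm <= spec.wall_fraction
    shape = spec.shape
    aorta_mask = inside.reshape(shape).astype(np.uint8)
    lumen_mask = lumen.reshape(shape).astype(np.uint8)
    wall_mask = (aorta_mask & ~lumen_mask.astype(bool)).astype(np.uint8)
    labels = np.where(inside, nearest_cls, 0).reshape(shape).astype(np.int64)

    plaque_mask, object_map = _place_plaques(spec, rng, segs, coords, dist_norm, labels)
    # plaque is part of aorta tissue; anatomy labels must cover it
    aorta_mask = (aorta_mask | (object_map > 0)).astype(np.uint8)

    table = _object_table(spec, object_map, labels)
    cd45_mask = _cd45_mask(spec, object_map, table)

    levels = spec.intensity_levels
    af = np.full(shape, levels["background"], dtype=np.float64)
    af[lumen_mask > 0] = levels["lumen"]
    af[wall_mask > 0] = levels["wall"]
    af[plaque_mask > 0] = levels["plaque"]
    cd = np.full(shape, levels["background"], dtype=np.float64)
    cd[cd45_mask > 0] = levels["cd45"]
    if spec.noise_sd > 0:
        af += rng.normal(0.0, spec.noise_sd, size=shape)
        cd += rng.normal(0.0, spec.noise_sd, size=shape)
    af = np.clip(af, 0, 65535).astype(np.uint16)
    cd = np.clip(cd, 0, 65535).astype(np.uint16)

    truth = PhantomTruth(
        plaque_mask=plaque_mask,
        anatomy_labels=LabelVolume(labels=labels, spacing=spec.spacing),
        cd45_mask=cd45_mask,
        per_object_table=table,
        aorta_mask=aorta_mask,
        wall_mask=wall_mask,
        lumen_mask=lumen_mask,
        object_map=object_map,
    )
    af_stack = VolumeStack(voxels=af, spacing=spec.spacing, channel="autofluorescence")
    cd_stack = VolumeStack(voxels=cd, spacing=spec.spacing, channel="cd45")
    return af_stack, cd_stack, truth


def _place_plaques(spec, rng, segs, coords, dist_norm, labels):
    """Place ``n_plaques`` non-touching wall-attached ellipsoids; returns
    (plaque mask, integer object map with ids 1..n)."""
    shape = spec.shape
    object_map = np.zeros(shape, dtype=np.int64)
    if spec.n_plaques == 0:
        return object_map.astype(np.uint8), object_map
    weights = spec.plaque_compartment_weights
    seg_by_cls = {}
    for pts, cls, radius in segs:
        if cls > 0:
            seg_by_cls.setdefault(cls, []).append((pts, radius))
    names = [n for n in weights if CLASS_IDS[n] in seg_by_cls]
    probs = np.array([weights[n] for n in names], dtype=float)
    probs /= probs.sum()
    inside = (dist_norm <= 1.0).reshape(shape)

    placed = []  # (center, max_semiaxis)
    rmin, rmax = spec.plaque_radius_range_um
    zz = coords[:, 0].reshape(shape)
    yy = coords[:, 1].reshape(shape)
    xx = coords[:, 2].reshape(shape)
    obj_id = 0
    attempts = 0
    while obj_id < spec.n_plaques:
        attempts += 1
        if attempts > 500 * spec.n_plaques:
            raise PhantomSpecError(
                f"n_plaques: could not place {spec.n_plaques} non-touching plaques "
                "on this grid; reduce n_plaques or the plaque radii"
            )
        cls = CLASS_IDS[names[rng.choice(len(names), p=probs)]]
        pts, tube_r = seg_by_cls[cls][0]
        i = rng.integers(1, len(pts) - 1)
        p = pts[i]
        tangent = pts[min(i + 1, len(pts) - 1)] - pts[max(i - 1, 0)]
        tangent = tangent / (np.linalg.norm(tangent) + 1e-12)
        # random unit normal to the centerline -> attach point on the inner wall
        v = rng.normal(size=3)
        v -= v.dot(tangent) * tangent
        v /= np.linalg.norm(v) + 1e-12
        base_r = rng.uniform(rmin, rmax)
        semi = base_r * rng.uniform(0.75, 1.25, size=3)
        semi = np.maximum(semi, np.asarray(spec.spacing))
        center = p + (v * tube_r * spec.wall_fraction if spec.plaque_wall_attachment
                      else np.zeros(3))
        if any(np.linalg.norm(center - c) < m + semi.max() + 2 * max(spec.spacing)
               for c, m in placed):
            continue
        ell = (((zz - center[0]) / semi[0]) ** 2
               + ((yy - center[1]) / semi[1]) ** 2
               + ((xx - center[2]) / semi[2]) ** 2) <= 1.0
        vox = ell & inside & (object_map == 0)
        if not vox.any():
            continue
        obj_id += 1
        object_map[vox] = obj_id
        placed.append((center, semi.max()))
    return (object_map > 0).astype(np.uint8), object_map


def _object_table(spec, object_map, labels) -> pd.DataFrame:
    rows = []
    voxel_vol_mm3 = float(np.prod(spec.spacing)) * 1e-9
    for oid in range(1, int(object_map.max()) + 1):
        sel = object_map == oid
        count = int(sel.sum())
        lab = labels[sel]
        vals, cnts = np.unique(lab, return_counts=True)
        # majority anatomy class; ties broken toward the lowest class id
        best = vals[np.lexsort((vals, -cnts))][0]
        rows.append({
            "object_id": oid,
            "voxel_count": count,
            "volume_mm3": count * voxel_vol_mm3,
            "compartment": CLASS_MAP[int(best)],
        })
    return pd.DataFrame(rows, columns=["object_id", "voxel_count", "volume_mm3", "compartment"])


def _cd45_mask(spec, object_map, table) -> np.ndarray:
    cd45 = np.zeros(object_map.shape, dtype=np.uint8)
    if table.empty:
        return cd45
    if spec.cd45_mode == "full-infiltration":
        return (object_map > 0).astype(np.uint8)
    for _, row in table.iterrows():
        sel = object_map == row.object_id
        vol_um3 = row.volume_mm3 * 1e9
        eq_radius = (3.0 * vol_um3 / (4.0 * math.pi)) ** (1.0 / 3.0)
        if eq_radius <= spec.rim_radius_cutoff_um:
            cd45[sel] = 1
        else:
            # peripheral rim: voxels within rim_thickness of the object surface
            depth = ndimage.distance_transform_edt(sel, sampling=spec.spacing)
            cd45[sel & (depth <= spec.rim_thickness_um)] = 1
    return cd45


@dataclass
class SliceDataset:
    """Every ``stride``-th z-slice of a stack with its plaque mask."""

    images: list
    masks: list
    indices: list
    annotation_spacing_um: float


def slice_dataset(stack: VolumeStack, plaque_mask: np.ndarray, stride: int) -> SliceDataset:
    """Extract every ``stride``-th z-slice and its mask (sparse annotation).

    With stride 5 at 8 µm z-steps the inter-annotation spacing is 40 µm,
    the protocol used for manual volumetry.
    """
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    idx = list(range(0, stack.shape[0], stride))
    return SliceDataset(
        images=[stack.voxels[i] for i in idx],
        masks=[np.asarray(plaque_mask[i]) for i in idx],
        indices=idx,
        annotation_spacing_um=stride * stack.spacing[0],
    )


def phantom_cohort(n: int, seed: int = 0, **overrides) -> list:
    """Generate ``n`` phantoms with varied plaque load (seeded); returns a
    list of (spec, autofluorescence, cd45, truth) tuples.

    Plaque count and radii vary across phantoms so cohort-level volumes span
    a realistic dynamic range.
    """
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        params = dict(
            n_plaques=int(rng.integers(2, 9)),
            plaque_radius_range_um=(12.0, float(rng.uniform(25.0, 45.0))),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        params.update(overrides)
        spec = PhantomSpec(**params)
        af, cd, truth = generate_phantom(spec)
        out.append((spec, af, cd, truth))
    return out
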