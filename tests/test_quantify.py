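"""Volumetry oracles: analytic volumes, connectivity cases, conservation."""

import math

import numpy as np
import pytest

from athero3d.imgio import LabelVolume
from athero3d.quantify import (cd45_positive_mask, cd45_quantify, compartment_report,
                               objects_table, plaque_objects, plaque_volume,
                               sparse_volume_estimate)


class TestPlaqueVolume:
    def test_million_voxels_at_10um_is_one_mm3(self):
        mask = np.ones((100, 100, 100), dtype=np.uint8)
        assert plaque_volume(mask, (10, 10, 10)) == pytest.approx(1.0)

    def test_empty_mask(self):
        assert plaque_volume(np.zeros((4, 4, 4)), (8, 4.8, 4.8)) == 0.0

    def test_digitised_sphere_near_analytic(self):
        # r = 40 µm at 8 µm isotropic: (4/3)π 40³ µm³ = 2.68e-4 mm³
        r_um, sp = 40.0, 8.0
        ax = (np.arange(16) - 7.5) * sp
        zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
        sphere = (zz**2 + yy**2 + xx**2) <= r_um**2
        vol = plaque_volume(sphere, (sp, sp, sp))
        analytic = 4.0 / 3.0 * math.pi * r_um**3 * 1e-9
        assert vol == pytest.approx(analytic, rel=0.10)

    def test_missing_spacing_rejected(self):
        with pytest.raises(ValueError):
            plaque_volume(np.ones((2, 2, 2)), None)


class TestPlaqueObjects:
    def test_two_disjoint_cubes(self):
        mask = np.zeros((10, 10, 10), dtype=np.uint8)
        mask[1:3, 1:3, 1:3] = 1
        mask[6:9, 6:9, 6:9] = 1
        objects, _ = plaque_objects(mask, None, (1, 1, 1))
        assert sorted(o.voxel_count for o in objects) == [8, 27]

    def test_corner_touching_cubes_connectivity(self):
        mask = np.zeros((6, 6, 6), dtype=np.uint8)
        mask[1:3, 1:3, 1:3] = 1
        mask[3:5, 3:5, 3:5] = 1   # touches only at the corner voxel diagonal
        obj26, _ = plaque_objects(mask, None, (1, 1, 1), connectivity=26)
        obj6, _ = plaque_objects(mask, None, (1, 1, 1), connectivity=6)
        assert len(obj26) == 1 and len(obj6) == 2

    def test_volume_conservation_exact(self, small_phantom):
        spec, af, cd, truth = small_phantom
        objects, _ = plaque_objects(truth.plaque_mask, truth.anatomy_labels, spec.spacing)
        assert sum(o.volume_mm3 for o in objects) == pytest.approx(
            plaque_volume(truth.plaque_mask, spec.spacing), abs=0)

    def test_recovers_phantom_truth_table(self, small_phantom):
        spec, af, cd, truth = small_phantom
        objects, _ = plaque_objects(truth.plaque_mask, truth.anatomy_labels, spec.spacing)
        got = objects_table(objects).sort_values("voxel_count").reset_index(drop=True)
        want = truth.per_object_table.sort_values("voxel_count").reset_index(drop=True)
        assert list(got.voxel_count) == list(want.voxel_count)
        assert list(got.compartment) == list(want.compartment)

    def test_majority_tie_breaks_to_lowest_class(self):
        mask = np.zeros((4, 4, 4), dtype=np.uint8)
        mask[1, 1, 1:3] = 1
        lab = np.zeros((4, 4, 4), dtype=np.int64)
        lab[1, 1, 1], lab[1, 1, 2] = 2, 1   # ARCH vs DESC, one voxel each
        objects, _ = plaque_objects(mask, LabelVolume(labels=lab, spacing=(1, 1, 1)), (1, 1, 1))
        assert objects[0].compartment == "DESC"


class TestSparseVolume:
    def test_direct_arithmetic(self):
        # 100 px at 4.8x4.8 µm, stride 5 at 8 µm z: 100*23.04*40*1e-9 mm³
        m = np.zeros((20, 20))
        m.flat[:100] = 1
        vol = sparse_volume_estimate({0: m}, stride=5, spacing=(8, 4.8, 4.8))
        assert vol == pytest.approx(9.216e-5)

    def test_stride_one_equals_plaque_volume(self, small_phantom):
        spec, af, cd, truth = small_phantom
        annotated = {i: truth.plaque_mask[i] for i in range(truth.plaque_mask.shape[0])}
        assert sparse_volume_estimate(annotated, 1, spec.spacing) == pytest.approx(
            plaque_volume(truth.plaque_mask, spec.spacing), abs=0)

    def test_stride_five_within_ten_percent(self):
        # smooth, large plaques so 40 µm slabs sample the shape adequately
        from athero3d.phantom import PhantomSpec, generate_phantom

        spec = PhantomSpec(seed=6, n_plaques=5, plaque_radius_range_um=(35.0, 55.0))
        _, _, truth = generate_phantom(spec)
        annotated = {i: truth.plaque_mask[i]
                     for i in range(0, truth.plaque_mask.shape[0], 5)}
        est = sparse_volume_estimate(annotated, 5, spec.spacing)
        full = plaque_volume(truth.plaque_mask, spec.spacing)
        assert est == pytest.approx(full, rel=0.10)

    def test_inconsistent_dims_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            sparse_volume_estimate({0: np.zeros((4, 4)), 5: np.zeros((5, 5))}, 5, (8, 5, 5))


class TestCD45:
    def test_zero_channel_zero_volumes(self, small_phantom):
        spec, af, cd, truth = small_phantom
        zero = np.zeros_like(truth.plaque_mask, dtype=np.uint16)
        objects, report = cd45_quantify(zero, truth.plaque_mask, truth.anatomy_labels,
                                        spec.spacing)
        assert all(o.cd45_volume_mm3 == 0 for o in objects)

    def test_cd45_equal_to_plaque_gives_full_volumes(self, small_phantom):
        spec, af, cd, truth = small_phantom
        chan = truth.plaque_mask.astype(np.uint16) * 30000
        objects, _ = cd45_quantify(chan, truth.plaque_mask, truth.anatomy_labels,
                                   spec.spacing, method="fixed:15000")
        for o in objects:
            assert o.cd45_volume_mm3 == pytest.approx(o.volume_mm3, abs=0)

    def test_cd45_mask_identical_to_plaque_mask(self, small_phantom):
        spec, af, cd, truth = small_phantom
        objects, _ = plaque_objects(truth.plaque_mask, truth.anatomy_labels,
                                    spec.spacing, cd45_mask=truth.plaque_mask)
        for o in objects:
            assert o.cd45_volume_mm3 == pytest.approx(o.volume_mm3, abs=0)

    def test_peripheral_rim_ratio_decreases_with_volume(self):
        # many plaques spanning the size cutoff: CD45 fraction must fall with size
        from athero3d.phantom import PhantomSpec, generate_phantom
        from athero3d.stats import spearman

        spec = PhantomSpec(seed=9, n_plaques=10, plaque_radius_range_um=(14.0, 45.0),
                           cd45_mode="peripheral-rim", noise_sd=0.0)
        af, cd, truth = generate_phantom(spec)
        objects, _ = cd45_quantify(cd, truth.plaque_mask, truth.anatomy_labels,
                                   spec.spacing, method="fixed:15000")
        vols = [o.volume_mm3 for o in objects]
        ratios = [o.cd45_volume_mm3 / o.volume_mm3 for o in objects]
        r, _ = spearman(vols, ratios)
        assert len(objects) >= 10 and r < 0

    def test_no_plaque_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="no plaque"):
            out = cd45_positive_mask(np.ones((4, 4, 4), dtype=np.uint16),
                                     np.zeros((4, 4, 4)))
        assert out.sum() == 0


class TestCompartmentReport:
    def test_totals_conserved(self, small_phantom):
        spec, af, cd, truth = small_phantom
        objects, _ = plaque_objects(truth.plaque_mask, truth.anatomy_labels, spec.spacing)
        rep = compartment_report(objects)
        total = rep.loc[rep.compartment == "TOTAL", "plaque_volume_mm3"].iloc[0]
        parts = rep.loc[rep.compartment != "TOTAL", "plaque_volume_mm3"].sum()
        # voxel counts conserve exactly; volumes only up to float summation order
        assert rep.loc[rep.compartment != "TOTAL", "object_count"].sum() == \
            rep.loc[rep.compartment == "TOTAL", "object_count"].iloc[0]
        assert parts == pytest.approx(total, rel=1e-12)
        assert total == pytest.approx(plaque_volume(truth.plaque_mask, spec.spacing), rel=1e-12)

    def test_arch_bca_concentration_ranks_first(self):
        from athero3d.phantom import PhantomSpec, generate_phantom

        spec = PhantomSpec(seed=4, n_plaques=5, plaque_radius_range_um=(12.0, 28.0),
                           plaque_compartment_weights={"ARCH": 0.5, "BCA": 0.5})
        af, cd, truth = generate_phantom(spec)
        objects, _ = plaque_objects(truth.plaque_mask, truth.anatomy_labels, spec.spacing)
        rep = compartment_report(objects)
        comp = rep[~rep.compartment.isin(["TOTAL", "OTHER"])]
        top2 = set(comp.nlargest(2, "plaque_volume_mm3").compartment)
        assert top2 == {"ARCH", "BCA"}
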