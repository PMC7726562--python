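"""End-to-end orchestration: simulate -> preprocess -> plaque inference ->
anatomy labelling -> quantification -> statistics.

Every run writes its artifacts (masks, label volumes, per-object and
per-compartment CSVs, stats report) plus a provenance log (config hash,
seed, package version) into the output directory.  Fixed seed on one CPU
thread gives identical CSV outputs run to run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import anatomy_unet, atlas_reg, imgio, phantom, plaque_unet, preprocess, quantify, stats
from .config import PipelineConfig

log = logging.getLogger("athero3d")


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def simulate(config: PipelineConfig, out_dir: Path) -> list:
    """Generate the phantom cohort and write stacks + ground truth to disk."""
    sim = config.simulate
    overrides = dict(shape=tuple(sim.shape), spacing=tuple(sim.spacing),
                     noise_sd=sim.noise_sd, cd45_mode=sim.cd45_mode)
    cohort = phantom.phantom_cohort(sim.n_phantoms, seed=config.seed, **overrides)
    if sim.n_plaques is not None:
        cohort = []
        rng = np.random.default_rng(config.seed)
        for _ in range(sim.n_phantoms):
            spec = phantom.PhantomSpec(n_plaques=sim.n_plaques,
                                       seed=int(rng.integers(0, 2**31 - 1)), **overrides)
            af, cd, truth = phantom.generate_phantom(spec)
            cohort.append((spec, af, cd, truth))
    for k, (spec, af, cd, truth) in enumerate(cohort):
        d = out_dir / f"phantom_{k:02d}"
        imgio.write_stack(af, d / "autofluorescence.tif")
        imgio.write_stack(cd, d / "cd45.tif")
        imgio.write_mask(truth.plaque_mask, spec.spacing, d / "plaque_truth.tif")
        imgio.write_labels(truth.anatomy_labels, d / "anatomy_truth.tif")
        truth.per_object_table.to_csv(d / "objects_truth.csv", index=False)
    log.info("simulated %d phantoms", len(cohort))
    return cohort


def _slice_pairs(af, truth, config, rng, limit=None):
    pre = preprocess.PreprocSpec2D(target_size=tuple(config.preprocess.target_size),
                                   clip_limit=config.preprocess.clip_limit,
                                   tile_grid=tuple(config.preprocess.tile_grid))
    ds = phantom.slice_dataset(af, truth.plaque_mask, stride=1)
    pairs = []
    h, w = pre.target_size[1], pre.target_size[0]
    for img, msk in zip(ds.images, ds.masks):
        pm = preprocess.resize_volume(msk[None], (1, h, w), kind="mask")[0]
        pairs.append((preprocess.preprocess_slice(img, pre), pm))
    if limit is not None and len(pairs) > limit:
        idx = rng.choice(len(pairs), size=limit, replace=False)
        pairs = [pairs[i] for i in sorted(idx)]
    return pairs, pre


def run_pipeline(config: PipelineConfig, output_dir=None) -> Path:
    """Run all stages in order; returns the output directory.

    Any stage failure propagates after the failing stage is logged; partial
    outputs from completed stages stay on disk.
    """
    config.validate()
    out_dir = Path(output_dir or config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    provenance = {"version": __version__, "seed": config.seed,
                  "config_sha256": _config_hash(config), "started": time.strftime("%FT%T")}
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    rng = np.random.default_rng(config.seed)

    stage = "simulate"
    try:
        cohort = simulate(config, out_dir)

        stage = "train-plaque"
        if config.plaque.checkpoint:
            model = plaque_unet.load_model(config.plaque.checkpoint)
            _, pre = _slice_pairs(cohort[0][1], cohort[0][3], config, rng, limit=1)
        else:
            pairs, pre = _slice_pairs(cohort[0][1], cohort[0][3], config, rng)
            n_val = max(1, len(pairs) // 5)
            net = plaque_unet.UNetSpec2D(
                depth=config.plaque.depth, base_filters=config.plaque.base_filters,
                input_size=(pre.target_size[1], pre.target_size[0]),
                lr=config.plaque.lr, max_epochs=config.plaque.max_epochs,
                patience=config.plaque.patience, batch_size=config.plaque.batch_size,
                threshold=config.plaque.threshold, seed=config.seed)
            split = plaque_unet.DatasetSplit(train=pairs[n_val:], validation=pairs[:n_val])
            aug = plaque_unet.AugmentSpec() if config.plaque.augment else None
            res = plaque_unet.train(split, net, aug)
            model = res.model
            res.history.to_csv(out_dir / "plaque_training_history.csv", index=False)
            plaque_unet.save_model(model, net, out_dir / "plaque_model.npz")

        stage = "anatomy-atlas-build"
        pre3d = preprocess.PreprocSpec3D(
            registration_size=tuple(config.preprocess.registration_size),
            network_size=tuple(config.preprocess.network_size),
            binarization=config.preprocess.binarization)
        atlases = []
        for k in range(min(config.anatomy.n_atlases, len(cohort))):
            spec_k, af_k, _, truth_k = cohort[k]
            dist, binm, sp = preprocess.prepare_for_registration(af_k, pre3d)
            lab = preprocess.resize_volume(truth_k.anatomy_labels.labels,
                                           pre3d.registration_size, kind="labels")
            atlases.append(atlas_reg.AtlasEntry(atlas_id=k, distance=dist,
                                                labels=lab.astype(np.int64), spacing=sp))

        per_animal_rows = []
        for k, (spec_k, af_k, cd_k, truth_k) in enumerate(cohort):
            stage = f"predict-plaque[{k}]"
            plaque_mask = plaque_unet.predict_stack(model, af_k, pre,
                                                    threshold=config.plaque.threshold)
            d = out_dir / f"phantom_{k:02d}"
            imgio.write_mask(plaque_mask, spec_k.spacing, d / "plaque_pred.tif")

            stage = f"anatomy[{k}]"
            dist, binm, sp = preprocess.prepare_for_registration(af_k, pre3d)
            if config.anatomy.method == "atlas":
                params = atlas_reg.RegistrationParams(
                    iterations=tuple(config.anatomy.iterations))
                labels_reg, _ = atlas_reg.label_by_atlas(dist, binm, sp, atlases, params)
            else:
                small = preprocess.resize_volume(binm, pre3d.network_size, kind="mask")
                net3 = anatomy_unet.UNetSpec3D(
                    input_size=tuple(pre3d.network_size), depth=config.anatomy.depth,
                    base_filters=config.anatomy.base_filters, lr=config.anatomy.lr,
                    max_epochs=config.anatomy.max_epochs, seed=config.seed)
                model3 = _get_anatomy_model(config, cohort, pre3d, net3)
                pred = anatomy_unet.predict_anatomy(model3, small)
                labels_reg = anatomy_unet.upscale_and_postprocess(pred, binm, sp)
            # carry the registration-grid labels back to the native grid
            lab_native = preprocess.resize_volume(labels_reg.labels, af_k.shape,
                                                  kind="labels")
            labels_native = imgio.LabelVolume(labels=lab_native.astype(np.int64),
                                              spacing=spec_k.spacing)
            imgio.write_labels(labels_native, d / "anatomy_pred.tif")

            stage = f"quantify[{k}]"
            cd45_pos = quantify.cd45_positive_mask(cd_k, plaque_mask,
                                                   config.quantify.cd45_method)
            objects, _ = quantify.plaque_objects(plaque_mask, labels_native,
                                                 spec_k.spacing,
                                                 connectivity=config.quantify.connectivity,
                                                 cd45_mask=cd45_pos)
            quantify.objects_table(objects).to_csv(d / "objects.csv", index=False)
            rep = quantify.compartment_report(objects)
            rep.to_csv(d / "compartments.csv", index=False)
            row = {"animal_id": f"phantom_{k:02d}",
                   "genotype": "phantom",
                   "diet": "western" if k % 2 else "chow",
                   "total_volume_mm3": float(rep.loc[rep.compartment == "TOTAL",
                                                     "plaque_volume_mm3"].iloc[0])}
            for comp in imgio.COMPARTMENTS:
                sel = rep.compartment == comp
                row[f"volume_{comp}_mm3"] = float(rep.loc[sel, "plaque_volume_mm3"].iloc[0])
                row[f"cd45_{comp}_mm3"] = float(rep.loc[sel, "cd45_volume_mm3"].iloc[0])
            per_animal_rows.append(row)

        stage = "stats"
        cohort_table = pd.DataFrame(per_animal_rows)
        cohort_table.to_csv(out_dir / "cohort_measurements.csv", index=False)
        if config.stats.enabled and cohort_table["diet"].nunique() >= 2:
            report = stats.run_paper_analyses(cohort_table)
            report.to_csv(out_dir / "stats_report.csv", index=False)
    except Exception:
        log.exception("pipeline failed at stage %s", stage)
        (out_dir / "FAILED_STAGE.txt").write_text(stage)
        raise
    return out_dir


_ANATOMY_CACHE: dict = {}


def _get_anatomy_model(config, cohort, pre3d, net3):
    """Train (once per run) a 3D anatomy net on the simulated cohort."""
    key = id(cohort)
    if key in _ANATOMY_CACHE:
        return _ANATOMY_CACHE[key]
    samples = []
    for k, (spec_k, af_k, _, truth_k) in enumerate(cohort):
        binm = preprocess.fill_binary(preprocess.binarize_volume(af_k, pre3d.binarization))
        small = preprocess.resize_volume(binm, pre3d.network_size, kind="mask")
        lab = preprocess.resize_volume(truth_k.anatomy_labels.labels, pre3d.network_size,
                                       kind="labels")
        samples.append(anatomy_unet.Sample3D(sample_id=f"p{k}", binary=small,
                                             labels=lab.astype(np.int64), group="phantom"))
    plan = anatomy_unet.CrossValPlan(folds=[(samples[-1].sample_id,)])
    folds = anatomy_unet.train_anatomy(samples, plan, net3)
    _ANATOMY_CACHE[key] = folds[0].model
    return folds[0].model
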