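"""Per-compartment plaque volumetry, CD45 composition, and the cohort-level
nonparametric statistics.

Uses ground-truth masks (no model inference) to show the quantification
and statistics layers in isolation: individual plaque objects, volumes per
anatomical compartment, CD45-in-plaque volume, then a two-diet cohort
contrast with Mann-Whitney tests and BH-FDR correction.
"""

import numpy as np
import pandas as pd

from athero3d.imgio import COMPARTMENTS
from athero3d.phantom import PhantomSpec, generate_phantom
from athero3d.quantify import cd45_quantify
from athero3d.stats import run_paper_analyses

spec = PhantomSpec(seed=7, n_plaques=8, plaque_radius_range_um=(14.0, 45.0))
af, cd45, truth = generate_phantom(spec)
objects, report = cd45_quantify(cd45, truth.plaque_mask, truth.anatomy_labels,
                                spec.spacing)
print("per-compartment report (mm³):")
print(report.round(6).to_string(index=False))
print("\nCD45 fraction falls with plaque size (rim-restricted infiltration):")
for o in sorted(objects, key=lambda o: o.volume_mm3):
    print(f"  object {o.object_id}: volume {o.volume_mm3:.6f}, "
          f"CD45 fraction {o.cd45_volume_mm3 / o.volume_mm3:.2f}")

# a synthetic two-diet cohort: western-diet animals carry ~4x the plaque
rng = np.random.default_rng(0)
rows = []
for diet, scale in (("chow", 1.0), ("western", 4.0)):
    for i in range(10):
        total = rng.lognormal(np.log(0.02 * scale), 0.4)
        row = {"animal_id": f"{diet}{i}", "genotype": "ApoE-/-", "diet": diet,
               "total_volume_mm3": total}
        for comp in COMPARTMENTS:
            row[f"volume_{comp}_mm3"] = total * rng.uniform(0.05, 0.4)
        rows.append(row)
analysis = run_paper_analyses(pd.DataFrame(rows))
print("\ncohort contrasts (q = BH-FDR adjusted p within each family):")
cols = ["family", "contrast", "test", "p_value", "q_value", "significant"]
print(analysis[cols].round(4).to_string(index=False))
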