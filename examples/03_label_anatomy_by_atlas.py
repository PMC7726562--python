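"""Label the aortic tree of a deformed sample by multi-atlas registration.

Builds eight phantom atlases, deforms one of them by a known rigid +
b-spline transform, and recovers it: the sample is registered to every
atlas (rigid -> affine -> b-spline on distance-encoded filled binaries) and
the best dice wins.  Takes ~3-4 minutes.
"""

from athero3d.experiments import registration_recovery_experiment

out = registration_recovery_experiment(seed=0)
print("dice of the warped atlas binary against the sample, per atlas:")
for atlas_id, dice in sorted(out["per_atlas_dice"].items()):
    marker = " <- chosen" if atlas_id == out["chosen_atlas"] else ""
    print(f"  atlas {atlas_id}: {dice:.4f}{marker}")
print(f"\nsample was atlas {out['expected_atlas']} under a known deformation; "
      f"registration recovered overlap dice {out['dice']:.4f}")
print(f"post-processed labels cover the sample mask exactly: {out['coverage_exact']}")
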