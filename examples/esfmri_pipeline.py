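"""Block-design es-fMRI analysis of a synthetic stimulation cohort.

Simulates six subjects' BOLD runs (8 s ON / 26 s OFF x 10, TR 2 s) with two
ROIs carrying a ~1% hemodynamic response on AR(1) noise, runs the
single-subject pipeline (detrend + band-pass + smoothing -> GLM -> p<0.001
with cluster-extent correction) and reports group-level activation.
"""

from adedbs import esfmri as fx
from adedbs import simulate as sim

grid = (32, 32, 6)
atlas = sim.make_roi_atlas(
    grid,
    {1: (6, 12, 6, 12, 1, 4),    # stimulated-target ROI, 1.0% signal change
     2: (20, 26, 18, 26, 2, 5),  # downstream ROI, 1.2%
     3: (3, 8, 24, 29, 0, 3)},   # control ROI, no programmed response
)
datasets = [
    sim.generate_bold_dataset(
        sim.BoldSimParams(grid=grid, active_rois={1: 1.0, 2: 1.2}, seed=50 + s), atlas
    )
    for s in range(6)
]

pmap, fractions = fx.group_analysis(datasets)
print("mean relative activation volume per ROI (active voxels / ROI voxels):")
for label, frac in sorted(fractions.items()):
    seeded = "seeded" if label in (1, 2) else "control"
    print(f"  ROI {label} ({seeded}): {frac:.3f}")
print(f"voxels with all-subject coincident activation: {(pmap.p_active == 1.0).sum()}")
print(f"minimum cluster extent applied: {fx.DEFAULT_MIN_CLUSTER} voxels at p < 0.001")
print("\nSeeded ROIs should be close to fully active; the control ROI near zero -"
      "\nthe cluster threshold keeps isolated false-positive voxels out of the maps.")
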