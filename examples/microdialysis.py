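"""Microdialysis dopamine: baseline gating and percent-of-baseline response.

Simulates 20-min dialysate samples around stimulation onset with programmed
evoked rises (stimulation alone, then three ascending alcohol doses), checks
baseline stability, normalizes to the last four pre-stimulation samples and
prints the mean response per epoch.
"""

from adedbs import neurochem as nc
from adedbs import simulate as sim

series = sim.generate_dialysate_series(
    baseline_level=3.2,            # a.u. dopamine concentration
    stim_effect=1.3,               # +30% during the 60-min DBS-only epoch
    alcohol_effects=(1.5, 1.8, 2.2),  # multiplicative rise per 40-min dose epoch
    noise_cv=0.05,
    seed=7,
)

stable, window = nc.baseline_stable(series, k=4, tol_cv=0.15)
print(f"baseline stable: {stable} (last four pre-stimulation samples: "
      + ", ".join(f"{v:.2f}" for v in window) + ")")

normalized = nc.normalize_to_baseline(series)
summary = nc.evoked_response_summary(normalized)
print("\nmean dopamine per epoch, % of baseline:")
for epoch, value in summary.items():
    print(f"  {epoch:>18}: {value:6.1f}%")

print("\nThe baseline window averages exactly 100% by construction; the"
      "\ndose-dependent rise above it is the augmented alcohol-evoked dopamine"
      "\nrelease the study design is built to detect.")
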