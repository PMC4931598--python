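"""Drinking-microstructure analysis of a synthetic two-group relapse study.

Simulates sham- and DBS-group drinkometer recordings (6 baseline days, 4
post-abstinence days) with programmed relapse effects, fits the Fourier
drinking-pattern model per day, and prints amplitude/frequency fold changes
over baseline.  Frequency folds read as changes in "wanting" (approaches per
hour), amplitude folds as changes in "liking" (intake per approach).
"""

from adedbs import drinkometer as dk
from adedbs import simulate as sim

sham_params, dbs_params = sim.study_defaults()
cohort = sim.generate_cohort(sham_params, dbs_params, n_per_group=5, seed=2024)

summary = dk.relapse_pattern_summary(cohort, ade_day=6)
folds = dk.pattern_fold_changes(summary).set_index(["group", "bottle", "window"])

print("Fold change over baseline on the first post-abstinence day (ADE day 1):")
print(f"{'group':>6} {'bottle':>8} {'frequency':>10} {'amplitude':>10}")
for group in ("sham", "dbs"):
    for bottle in dk.BOTTLES:
        row = folds.loc[(group, bottle, "ade1")]
        print(
            f"{group:>6} {bottle:>8} {row['frequency_fold']:>10.2f} {row['amplitude_fold']:>10.2f}"
        )

print(
    "\nSham relapse is frequency-driven (more approaches to 10/20% ethanol);\n"
    "stimulation suppresses the frequency surge but raises the amount drunk\n"
    "per approach - the programmed 'liking' shift the metrics must recover."
)
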