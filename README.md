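# adedbs

Analysis pipeline for deep-brain-stimulation (DBS) experiments in the rat
alcohol-deprivation-effect (ADE) model of relapse, built as an importable
Python library with synthetic ground-truth data generators so that every
stage is testable end to end without animal data.

## The scientific problem

In rats with long-term voluntary alcohol access, re-presenting alcohol after
weeks of deprivation produces a transient surge of intake over baseline —
the alcohol-deprivation effect, the standard rodent relapse readout.
Chronic electrical stimulation of the nucleus accumbens shell (NAcs) can
change both *how often* an animal approaches the alcohol bottles
(incentive salience, "wanting") and *how much* it drinks per approach
(hedonic impact, "liking").  Characterizing such an effect requires several
independent measurement chains, each with its own analysis:

1. **Drinking microstructure** (`adedbs.drinkometer`).  A four-bottle
   drinkometer weighs liquid removal in 5-min bins at 0.01 g resolution.
   Each bottle's series y(t) on a measurement interval L is described by a
   truncated real Fourier series

   y(t) ≈ a₀ + Σₖ aₖ cos(2π νₖ t) + bₖ sin(2π νₖ t),  νₖ = k / L,

   fitted by least squares on the uniform grid (equivalently the DFT).  From
   the reconstruction, **frequency** = maximal-intake peaks per hour
   ("wanting") and **amplitude** = mean peak intake per 5-min bin
   ("liking"; ml/kg for water, g pure ethanol/kg for ethanol, using ethanol
   density 0.789 g/ml).  Baseline vs post-abstinence fold changes quantify
   the relapse effect.

2. **Stimulation field** (`adedbs.field_model`).  A 2D finite-element model
   of the electric potential in the NAcs cross-section: −div(σ∇V) = q with
   Dirichlet conditions (5.25 V on the 250-µm electrode contour, 0 V on the
   region outline, σ = 9.15×10⁻² S/m), E = −∇V, plus a damped scalar wave
   equation (εᵣ/c²)∂²u/∂t² + μ₀σ ∂u/∂t = div(μᵣ⁻¹∇u) time-stepped with
   implicit Newmark for the 130 Hz drive.  Meshing, an analytic-annulus
   validation, and activated-area extraction (|E| ≥ threshold) are included.

3. **es-fMRI** (`adedbs.esfmri`).  Block-design BOLD analysis (8 s ON /
   26 s OFF × 10, TR 2 s): linear detrend, 0.015–0.2 Hz band-pass, in-plane
   3×3 Gaussian smoothing (σ = 1.5), voxelwise GLM against a shifted-boxcar
   or gamma-HRF regressor, voxel threshold p < 0.001 with a Monte-Carlo
   calibrated minimum cluster extent (packaged default 14 voxels),
   across-subject activation probability maps and per-ROI relative
   activation volumes.

4. **Microdialysis** (`adedbs.neurochem`).  Dopamine dialysate at 20-min
   intervals; gating on four stable pre-stimulation samples, normalization
   to their mean (= 100 %), and epoch summaries across the DBS-only period
   and three ascending alcohol doses (0.5 / 1.0 / 1.5 g/kg at 40-min
   spacing).

5. **Inference** (`adedbs.stats`).  Two-way repeated-measures (mixed) ANOVA
   (between: stimulation; within: time) from first-principles sums of
   squares, Student–Newman–Keuls stepwise post hoc on studentized-range
   quantiles, two-way factorial ANOVA for tissue neurochemistry,
   tie-corrected Spearman correlation, and stereotaxic distance of electrode
   tips to the NAcs target (AP +1.6, ML ±0.8, DV −7.6 mm).

6. **Synthetic data** (`adedbs.simulate`).  Generators for all of the above
   with *programmed* effects (circadian bout drinking with known
   frequency/amplitude relapse multipliers, AR(1)-noise BOLD with known
   percent-signal-change ROIs, dialysate with known evoked rises, electrode
   placements with a known distance–effect slope), so every analysis can be
   verified closed loop.

## Worked example

`examples/drinking_patterns.py` simulates a sham and a stimulated cohort
(6 baseline days, 4 post-abstinence days, 5 animals/group) and prints the
fold change of both pattern metrics over baseline on the first
post-abstinence day:

```
 group   bottle  frequency  amplitude
  sham    water       1.00       1.00
  sham    etoh5       1.00       1.00
  sham   etoh10      14.00       1.00
  sham   etoh20      10.00       0.60
   dbs    water       1.00       1.01
   dbs    etoh5       5.00       1.60
   dbs   etoh10      13.00       1.90
   dbs   etoh20       2.00       2.40
```

Reading: unstimulated relapse is frequency-driven — a 14-fold (10 % ethanol)
and 10-fold (20 % ethanol) surge in approaches per hour with unchanged
per-approach intake.  Under stimulation the frequency surge at the strongest
solution collapses (10× → 2×) while the per-approach amplitude rises
(0.60× → 2.40×, a 4-fold amplitude contrast between groups): less "wanting",
more "liking".  These are exactly the multipliers programmed into the
generator, recovered by the Fourier metric chain.

The other scripts in `examples/` (`field_simulation.py`,
`esfmri_pipeline.py`, `microdialysis.py`, `electrode_stats.py`) each build a
small input, run one analysis chain and print what the numbers mean; e.g.
the field simulation reports a 28.7°-minimum-angle mesh of the NAcs outline,
the 0–5.25 V potential, the activated area shrinking from 91 % to 0 % of the
domain as the |E| threshold grows, and a < 10⁻¹² relative difference between
the 130 Hz wave solution at the drive peak and the static solution.

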