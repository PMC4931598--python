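# Methods

This note documents the models, numerical choices and limitations of the
`adedbs` pipeline, in the order of the analysis chains.

## Drinking-microstructure model

**Fit.**  Each bottle's 5-min intake series on the interval L is fitted with
a truncated real Fourier series by least squares on the uniform grid, which
coincides with the discrete Fourier transform; frequencies are νₖ = k/L.
The default harmonic order is K = N//2 (N samples), i.e. the interpolating
fit: drinking approaches are single-bin events, and the peaks-per-hour
metric must be able to represent rates up to the ~0.6 peaks/h seen during
relapse (≈15 peaks/day), which a low-order fit mathematically cannot (a
K-harmonic trigonometric polynomial has at most ~K/days local maxima per
day).  K is a smoothing parameter and fully configurable; lowering it
low-pass filters the pattern.

**Metrics.**  Peaks are local maxima of the reconstruction on the native
grid that are positive and reach at least `peak_threshold` (default 0.2) of
the global maximum; the threshold suppresses Gibbs ripples around discrete
bouts at reduced K and measurement noise at full K.  Plateaus count once,
at their first bin.  *Amplitude* is the mean peak height (the maximum is
available as an option), *frequency* the peak count divided by the record
length in hours.  Water metrics are ml/kg, ethanol metrics g pure
ethanol/kg (density 0.789 g/ml; the weighed solution is treated as
1 g/ml), converted from grams of liquid before fitting.

**Windows.**  Following the study layout, "baseline" averages per-day
metrics over the last six pre-deprivation days; "ADE day 1" is the first
post-abstinence day; "ADE days 2–4" averages the next three.  Fitting per
day (rather than one fit across the window) makes window means insensitive
to how integer daily bout counts distribute across days.

## Synthetic drinking generator

The generator is the study-conditions definition, not a tuning knob.  Each
animal/bottle has a programmed daily bout rate and per-bout dose; from the
deprivation end (`ade_day`) the rate scales by a frequency multiplier and
the dose by an amplitude multiplier — the ground truth the metrics must
recover.  Design choices:

* **Deterministic daily counts.**  Bout counts per day are the increments
  of the rounded cumulative rate, so a programmed rate is represented
  exactly in whole bouts and daily totals are exact (6 bouts × 0.5 g/kg =
  3.0 g/kg/day up to 0.01 g quantization).  Bout *times* are random draws
  from a cosine circadian intensity peaking mid dark phase — a
  count-conditioned inhomogeneous Poisson process.
* **Refractory gap.**  Bouts at one bottle are at least 10 min apart
  (a drinking approach lasts minutes), which also means every programmed
  bout is a distinct local maximum of the recorded series.
* **Noise and quantization.**  Gaussian sensor noise (default SD 0.01 g,
  the instrument's resolution scale) is added per bin, then the series is
  floored at zero (the sensor cannot record negative removal) and
  quantized to 0.01 g.
* **Defaults.**  Baseline 1.0 bout/day/bottle (0.042 peaks/h, the order of
  the published baseline frequencies); sham relapse multipliers 14× (10 %
  ethanol) and 10× (20 %) on frequency; stimulated-group multipliers with
  the frequency surge suppressed and amplitude raised, including the
  4-fold amplitude contrast on the 20 % bottle.  Integer post-relapse
  rates keep the programmed daily structure exactly representable.
* **Not modelled.**  Within-bout microstructure (lick rates), blood
  alcohol pharmacokinetics, inter-animal rate heterogeneity beyond the
  random bout times.  Passing recovery tests therefore shows the metric
  chain is correct for bout-structured data, not that real records are
  this clean.

Cohorts split per-animal random streams from one master seed via
`numpy.random.SeedSequence.spawn`, so results are reproducible and
parallelizable; both groups share baseline parameters (matched baseline by
construction).

## Finite-element field model

**Geometry and mesh.**  The domain is the annular region between a region
outline and an electrode contour (default: a 250-µm-diameter circle at the
stimulation site), both polygons in mm.  The packaged NAc-shell outline is
a synthetic, hand-constructed approximation at the right anatomical scale —
suitable for simulation and testing, not an atlas tracing; analytic
validation therefore uses exact annulus geometries.  Meshing resamples the
contours at the target size h, seeds the interior with a hexagonal lattice
kept clear of the boundaries (plus a movable offset ring where a contour is
sampled finer than h, so element sizes grade smoothly), Delaunay-
triangulates, restricts to the region and Laplacian-smooths interior nodes.
Minimum angles are measured (`Mesh.min_angle_deg`) and tested to exceed 20°
on the shipped geometries rather than guaranteed by construction.

**Elliptic problem.**  P1 elements for −div(σ∇V) = q with Dirichlet values
on both contours (defaults 5.25 V / 0 V, q = 0: the electrode acts purely
through its boundary potential).  E = −∇V is constant per element,
reported in V/m.  Validation: the annulus solution
V(r) = V₀ ln(r_out/r)/ln(r_out/r_in) is matched with relative L2 error
~10⁻⁴ at h = 0.02 mm, and halving h cuts the error ~5× (at least the
O(h²) rate); the discrete maximum principle holds for q = 0.

**Hyperbolic problem.**  The vector curl–curl equation is reduced to its
out-of-plane scalar component u:
(εᵣ/c²) M ü + μ₀σ M u̇ + μᵣ⁻¹ K u = 0 with the drive as a time-dependent
Dirichlet value.  Default integrator is Newmark (β = 1/4, γ = 1/2,
unconditionally stable, consistent mass); an explicit central-difference
scheme with lumped mass raises a configuration error with a suggested step
when the CFL limit is exceeded, and a lumped-mass Newmark option allows a
like-for-like cross-validation of the two integrators (they agree to
≲0.1 %).  Steps must resolve the drive (≥20 per period).

**Parameters.**  σ = 9.15×10⁻² S/m, εᵣ = 2.46×10⁶, μᵣ = 9.3×10⁻¹⁰ — the
gray-matter values at 130 Hz used to parameterize the original model.  The
permittivity/permeability entries carry absolute unit labels in the source
despite naming relative quantities; they are used verbatim as dimensionless
values rather than silently corrected, and are overridable.  A consequence
of these numbers is a transit/damping timescale far below the 130 Hz drive
period, so the driven solution tracks the static (Laplace) solution
essentially exactly — consistent with a field that decays with distance
from the electrode and vanishes toward the region boundary.

## es-fMRI chain

* **Regressors.**  Shifted boxcar (default forward shift 2 s, rounded to
  the TR grid with a warning) or boxcar ⊛ single-gamma HRF (shape 6,
  scale 1 s — a standard choice, configurable), peak-normalized so betas
  read as percent signal change on percent-scale data.
* **Preprocessing.**  Per-voxel linear detrend; temporal band-pass
  0.015–0.2 Hz as a sharp DFT mask (deterministic, exact band edges — the
  analysis names only the band, not a filter family); per-slice 3×3
  Gaussian smoothing (σ = 1.5 voxels, normalized kernel, nearest-edge
  handling).  Runs shorter than 20 volumes are rejected.
* **GLM.**  Voxelwise OLS on [regressor, intercept] without prewhitening
  (band-pass + GLM is the specified chain); t = β/se, one-sided
  (activation) p from the t distribution; zero-residual voxels are flagged
  saturated with capped t.  The null false-positive rate at p < 0.001 is
  calibrated to within Monte-Carlo error.
* **Cluster correction.**  Suprathreshold voxels (p < 0.001) are grouped
  with 6-connectivity (face adjacency; connectivity is not specified in
  the source and is configurable only in code) and clusters below the
  minimum extent removed.  The packaged default extent is 14 voxels — the
  Monte-Carlo-calibrated value for the 96×96×15 grid and this smoothing —
  and `mc_cluster_threshold` recomputes the threshold for any grid by
  simulation.  The simulation smooths noise with periodic boundaries so
  the smoothed field has uniform per-voxel variance and the voxelwise
  threshold stays exact; on small grids it matches an exhaustive
  connected-component enumeration oracle.
* **Group maps.**  Subject-level activation masks (p < 0.001, cluster
  ≥ 14) are averaged voxelwise into probability maps (exact rationals
  k/n) and summarized per ROI as active voxels / ROI voxels.

The BOLD generator uses AR(1) noise with a single autocorrelation (default
ρ = 0.3, SD 1 % of baseline) — adequate for desk-scale power checks, but
real scanner noise (drifts, physiology, motion) is richer; recovery tests
certify the analysis code, not acquisition robustness.

## Microdialysis

Samples every 20 min; stability requires the last four pre-stimulation
samples to have a coefficient of variation ≤ 0.15 (the source states
"stable" without a criterion; the tolerance is reported with the result).
Normalization divides by the mean of those four samples (× 100), making the
baseline-window mean exactly 100 %; it is idempotent and invariant to
positive rescaling of the raw data.  Alcohol doses are 0.5/1.0/1.5 g/kg at
40-min intervals after a 60-min stimulation-only epoch — the g/kg unit
follows the figure axis; an mg/kg rendering elsewhere in circulation is
treated as a typographical slip, and the series records the choice.

## Inference

* **Mixed ANOVA.**  Classical sums-of-squares decomposition for balanced
  designs: between-factor error is subjects-within-group, within and
  interaction use time × subjects-within-group.  Missing cells and
  unbalanced groups raise rather than impute.  No sphericity correction by
  default (uncorrected degrees of freedom are the reported convention
  here); the empirical type-I rate per factor is ~0.05 under the null.
* **SNK.**  Means sorted, stepwise studentized-range tests with
  span-dependent critical values from `scipy.stats.studentized_range`
  (numerically integrated, no hard-coded tables; validated against
  published 5 % points).  A non-significant span blocks all inner pairs,
  preserving SNK coherence.
* **Factorial ANOVA.**  Type III via model comparison with sum-to-zero
  coding; reduces to the classical decomposition when balanced, and
  tolerates the modestly unbalanced cells of real tissue tables.
* **Spearman.**  Pearson correlation of mid-ranks (tie-corrected);
  undefined (NaN with a warning) when a variable has zero rank variance.
* **Distances.**  Euclidean stereotaxic distance to the target; tips in
  the opposite hemisphere are reflected in ML first, with a warning.

The headline animal statistics of the original study (its F values, intake
curves, the ρ = 0.60 placement correlation) derive from unpublished raw
animal data and are not reproducible; the package ships the same analyses
applied to synthetic cohorts with programmed effects, plus the three
worked-example fold changes computable exactly from the published
drinking-pattern table.

## Problem sizes and determinism

Test-suite and acceptance runs use desk-scale sizes chosen for fast
feedback: cohorts of 5–8 animals/group over 10 days, BOLD grids of
32×32×6 (the full 96×96×15 grid is supported and used for the packaged
cluster default), 1500 cluster-threshold simulations, 5000 ANOVA null
replicates, FEM meshes up to ~36 000 nodes (h = 0.02 mm).  All randomness
flows from explicit seeds; identical seeds give bit-identical outputs.
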