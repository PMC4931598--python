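"""Synthetic ground-truth data for every stage of the pipeline.

The generators emulate the study's four data streams with *programmed* effects
so that each analysis stage can be tested closed-loop:

* home-cage drinkometer recordings (four bottles, 5-min bins, 0.01 g
  quantization) with a circadian bout pattern and a baseline -> relapse (ADE)
  jump whose frequency/amplitude multipliers are known;
* microdialysis dopamine series (20-min samples) with a stable baseline and
  stimulation / alcohol-dose evoked rises of known size;
* 4D BOLD runs with gamma-HRF block responses of known percent signal change
  in designated ROIs on AR(1) noise;
* electrode-tip placements whose distance to the stereotaxic target drives a
  programmed linear intake-change effect (negative correlation by default).

Every generator is a pure function of its parameters and seed; per-animal
random streams are split from one master seed via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .drinkometer import (
    BIN_MINUTES,
    BINS_PER_DAY,
    BOTTLES,
    CONCENTRATION,
    ETHANOL_DENSITY_G_PER_ML,
    DrinkometerSeries,
)
from .errors import ParameterError
from .esfmri import StimProtocol, build_regressor

QUANTUM_G = 0.01  # drinkometer resolution, grams

# stereotaxic target of the NAc shell: AP anterior to bregma, ML lateral to
# the midline, DV ventral to the dura (mm)
NACS_TARGET_MM = (1.6, 0.8, 7.6)


# ---------------------------------------------------------------------------
# drinkometer cohorts
# ---------------------------------------------------------------------------


@dataclass
class DrinkingSimParams:
    """Programmed drinking structure for one animal.

    ``bouts_per_day`` / ``bout_amount`` map bottle -> daily approach rate and
    per-bout dose (g ethanol/kg for ethanol bottles, ml/kg for water).  From
    ``ade_day`` on, rates scale by ``ade_frequency_multiplier`` and doses by
    ``ade_amplitude_multiplier`` — the ground truth the drinking-pattern
    metrics must recover.  ``noise_sd`` is sensor noise in grams per bin.
    """

    n_days: int = 10
    bouts_per_day: Mapping[str, float] = field(default_factory=dict)
    bout_amount: Mapping[str, float] = field(default_factory=dict)
    ade_day: int | None = 6
    ade_frequency_multiplier: Mapping[str, float] = field(default_factory=dict)
    ade_amplitude_multiplier: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 0.01
    body_weight: float = 450.0
    circadian_period_h: float = 24.0
    circadian_strength: float = 0.8
    dark_onset_h: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days <= 0:
            raise ParameterError("n_days must be positive")
        if self.body_weight <= 0:
            raise ParameterError("body_weight must be positive")
        if self.ade_day is not None and not 0 <= self.ade_day <= self.n_days:
            raise ParameterError("ade_day must lie within the recording")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        if not 0 <= self.circadian_strength <= 1:
            raise ParameterError("circadian_strength must be in [0, 1]")
        for m in (self.bouts_per_day, self.ade_frequency_multiplier, self.ade_amplitude_multiplier):
            if any(v < 0 for v in m.values()):
                raise ParameterError("rates and multipliers must be non-negative")


def study_defaults() -> tuple[DrinkingSimParams, DrinkingSimParams]:
    """Sham and DBS parameter sets mirroring the study's effect structure.

    Both groups share the baseline (matched by construction).  Multipliers
    encode the headline relapse effects: sham relapse raises the approach
    frequency ~14x (10 % ethanol) and ~10x (20 % ethanol); chronic NAc-shell
    stimulation suppresses that frequency surge but raises the per-approach
    amplitude, 4x over sham for the 20 % bottle.
    """
    base = dict(
        n_days=10,
        bouts_per_day={"water": 1.0, "etoh5": 1.0, "etoh10": 1.0, "etoh20": 1.0},
        bout_amount={"water": 1.0, "etoh5": 0.5, "etoh10": 0.5, "etoh20": 0.5},
        ade_day=6,
        noise_sd=0.01,
        body_weight=450.0,
    )
    sham = DrinkingSimParams(
        **base,
        ade_frequency_multiplier={"water": 1.0, "etoh5": 1.0, "etoh10": 14.0, "etoh20": 10.0},
        ade_amplitude_multiplier={"water": 1.0, "etoh5": 1.0, "etoh10": 1.0, "etoh20": 0.6},
    )
    dbs = DrinkingSimParams(
        **base,
        ade_frequency_multiplier={"water": 1.0, "etoh5": 5.0, "etoh10": 13.0, "etoh20": 2.0},
        ade_amplitude_multiplier={"water": 1.0, "etoh5": 1.6, "etoh10": 1.9, "etoh20": 2.4},
    )
    return sham, dbs


def _counts_per_day(rate: float, n_days: int) -> np.ndarray:
    """Deterministic per-day bout counts: cumulative rounding of the rate."""
    cum = np.round(rate * np.arange(n_days + 1)).astype(int)
    return np.diff(cum)


def _dose_to_grams(bottle: str, dose: float, body_weight_g: float) -> float:
    bw_kg = body_weight_g / 1000.0
    c = CONCENTRATION[bottle]
    if c == 0:
        return dose * bw_kg  # ml/kg -> ml -> g at ~1 g/ml
    return dose * bw_kg / (ETHANOL_DENSITY_G_PER_ML * c / 100.0)


def _circadian_weights(params: DrinkingSimParams) -> np.ndarray:
    """Relative bout intensity per 5-min bin of one day (peak mid dark phase)."""
    t_h = (np.arange(BINS_PER_DAY) + 0.5) * BIN_MINUTES / 60.0
    peak = params.dark_onset_h + 6.0
    w = 1.0 + params.circadian_strength * np.cos(
        2 * np.pi * (t_h - peak) / params.circadian_period_h
    )
    return np.clip(w, 0.0, None)


def _draw_bout_bins(rng: np.random.Generator, weights: np.ndarray, count: int) -> np.ndarray:
    """Sample ``count`` bins from the circadian intensity with a 10-min refractory gap."""
    w = weights.astype(float).copy()
    chosen = []
    for _ in range(count):
        total = w.sum()
        if total <= 0:
            break
        i = int(rng.choice(w.size, p=w / total))
        chosen.append(i)
        lo, hi = max(0, i - 2), min(w.size, i + 3)
        w[lo:hi] = 0.0  # refractory: no second bout within 10 min
    return np.asarray(sorted(chosen), dtype=int)


def generate_drinkometer_series(params: DrinkingSimParams) -> dict[str, DrinkometerSeries]:
    """Simulate one animal's four-bottle recording (grams of liquid per bin).

    Bout counts per day are deterministic (cumulative rounding of the
    programmed rate); bout times follow the circadian intensity, i.e. a
    count-conditioned inhomogeneous Poisson process with a 10-min refractory
    gap.  Gaussian sensor noise is added per bin, then the series is floored
    at 0 and quantized to 0.01 g.
    """
    rng = np.random.default_rng(params.seed)
    n_bins = params.n_days * BINS_PER_DAY
    t = np.arange(n_bins) * BIN_MINUTES
    weights = _circadian_weights(params)
    ade = params.n_days if params.ade_day is None else params.ade_day
    out: dict[str, DrinkometerSeries] = {}
    for bottle in BOTTLES:
        rate = params.bouts_per_day.get(bottle, 0.0)
        fmult = params.ade_frequency_multiplier.get(bottle, 1.0)
        amult = params.ade_amplitude_multiplier.get(bottle, 1.0)
        dose = params.bout_amount.get(bottle, 0.0)
        y = np.zeros(n_bins)
        counts = np.concatenate(
            [_counts_per_day(rate, ade), _counts_per_day(rate * fmult, params.n_days - ade)]
        )
        for day, count in enumerate(counts):
            if count == 0:
                continue
            grams = _dose_to_grams(bottle, dose * (amult if day >= ade else 1.0), params.body_weight)
            bins = _draw_bout_bins(rng, weights, count)
            np.add.at(y, day * BINS_PER_DAY + bins, grams)
        if params.noise_sd > 0:
            y = y + rng.normal(0.0, params.noise_sd, size=n_bins)
        y = np.round(np.clip(y, 0.0, None) / QUANTUM_G) * QUANTUM_G
        out[bottle] = DrinkometerSeries(
            animal_id="sim", bottle=bottle, t=t, y=y, body_weight=params.body_weight
        )
    return out


@dataclass
class CohortMember:
    animal_id: str
    group: str
    series: dict[str, DrinkometerSeries]
    params: DrinkingSimParams


def _child_seed(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1)[0] & 0x7FFFFFFF)


def generate_cohort(
    params_sham: DrinkingSimParams,
    params_dbs: DrinkingSimParams,
    n_per_group: int,
    seed: int = 0,
) -> list[CohortMember]:
    """Sham- and DBS-group recordings with per-animal split random streams.

    Baseline drinking parameters should be identical between the two parameter
    sets (groups are assigned so that mean baseline intake is matched); only
    post-deprivation multipliers differ.
    """
    if n_per_group < 2:
        raise ParameterError("need at least 2 animals per group")
    children = np.random.SeedSequence(seed).spawn(2 * n_per_group)
    cohort = []
    for g, params in (("sham", params_sham), ("dbs", params_dbs)):
        for i in range(n_per_group):
            child = children.pop(0)
            p = dataclasses.replace(params, seed=_child_seed(child))
            animal_id = f"{g}{i + 1:02d}"
            series = generate_drinkometer_series(p)
            for s in series.values():
                s.animal_id = animal_id
            cohort.append(CohortMember(animal_id, g, series, p))
    return cohort


def cohort_to_frame(cohort: Sequence[CohortMember]) -> pd.DataFrame:
    """Tidy long table: one row per (animal, bottle, sample)."""
    rows = []
    for m in cohort:
        for bottle, s in m.series.items():
            rows.append(
                pd.DataFrame(
                    {
                        "animal_id": m.animal_id,
                        "group": m.group,
                        "timestamp": s.t,
                        "bottle": bottle,
                        "value": s.y,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# microdialysis
# ---------------------------------------------------------------------------

SAMPLE_MINUTES = 20.0
DBS_EPOCH_MIN = 60.0
DOSE_EPOCH_MIN = 40.0
ALCOHOL_DOSES_G_PER_KG = (0.5, 1.0, 1.5)


def generate_dialysate_series(
    baseline_level: float,
    stim_effect: float = 1.0,
    alcohol_effects: Sequence[float] = (1.0, 1.0, 1.0),
    noise_cv: float = 0.0,
    seed: int = 0,
    n_baseline: int = 4,
):
    """Dopamine dialysate samples every 20 min around DBS onset (t = 0).

    ``stim_effect`` and ``alcohol_effects`` are multiplicative factors applied
    to the baseline level during the 60-min DBS-only epoch and each subsequent
    40-min alcohol-dose epoch (1.0 = no change).  Multiplicative Gaussian
    noise with coefficient of variation ``noise_cv`` is applied per sample.
    """
    from .neurochem import DialysateSeries  # local import to avoid a cycle

    if baseline_level <= 0:
        raise ParameterError("baseline_level must be positive")
    if n_baseline < 4:
        raise ParameterError("at least 4 baseline samples are required")
    rng = np.random.default_rng(seed)
    dose_times = DBS_EPOCH_MIN + DOSE_EPOCH_MIN * np.arange(len(alcohol_effects))
    t_end = dose_times[-1] + DOSE_EPOCH_MIN if len(alcohol_effects) else DBS_EPOCH_MIN
    t = np.arange(-SAMPLE_MINUTES * (n_baseline - 1), t_end + SAMPLE_MINUTES / 2, SAMPLE_MINUTES)
    level = np.full(t.size, float(baseline_level))
    level[(t > 0) & (t <= DBS_EPOCH_MIN)] = baseline_level * stim_effect
    for t0, eff in zip(dose_times, alcohol_effects):
        level[(t > t0) & (t <= t0 + DOSE_EPOCH_MIN)] = baseline_level * eff
    da = level.copy()
    if noise_cv > 0:
        da = level * np.clip(1.0 + noise_cv * rng.standard_normal(t.size), 0.0, None)
    return DialysateSeries(
        t=t,
        da=da,
        dbs_on=0.0,
        dose_times=dose_times,
        doses_g_per_kg=ALCOHOL_DOSES_G_PER_KG[: len(alcohol_effects)],
    )


# ---------------------------------------------------------------------------
# BOLD
# ---------------------------------------------------------------------------


@dataclass
class BoldSimParams:
    """Block-design BOLD simulation: grid, protocol and programmed activations.

    ``active_rois`` maps atlas labels to percent signal change; noise is AR(1)
    with per-sample SD ``noise_sd`` (same percent scale, baseline = 100).
    """

    grid: tuple[int, int, int] = (96, 96, 15)
    tr: float = 2.0
    protocol: StimProtocol | None = None
    active_rois: Mapping[int, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    ar1_rho: float = 0.3
    baseline: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ParameterError("tr must be positive")
        if not 0 <= self.ar1_rho < 1:
            raise ParameterError("ar1_rho must be in [0, 1)")
        if self.protocol is None:
            self.protocol = StimProtocol(on_s=8.0, off_s=26.0, repeats=10, tr=self.tr)
        if not all(np.isfinite(list(self.active_rois.values()) or [0.0])):
            raise ParameterError("effect sizes must be finite")


@dataclass
class BOLDDataset:
    data: np.ndarray  # (x, y, z, t)
    tr: float
    protocol: StimProtocol
    atlas: np.ndarray  # (x, y, z) integer ROI labels

    def to_nifti(self):
        import nibabel as nib

        return nib.Nifti1Image(self.data, affine=np.eye(4))


def make_roi_atlas(grid: tuple[int, int, int], rois: Mapping[int, tuple]) -> np.ndarray:
    """Integer-labelled box atlas: label -> (x0, x1, y0, y1, z0, z1) slices."""
    atlas = np.zeros(grid, dtype=np.int32)
    for label, (x0, x1, y0, y1, z0, z1) in rois.items():
        atlas[x0:x1, y0:y1, z0:z1] = label
    return atlas


def _ar1_noise(rng: np.random.Generator, shape_t: int, n_vox: int, rho: float, sd: float) -> np.ndarray:
    z = rng.standard_normal((n_vox, shape_t))
    if rho == 0:
        return sd * z
    e = np.empty_like(z)
    e[:, 0] = z[:, 0]
    innov = np.sqrt(1.0 - rho**2)
    for k in range(1, shape_t):
        e[:, k] = rho * e[:, k - 1] + innov * z[:, k]
    return sd * e


def generate_bold_dataset(params: BoldSimParams, roi_atlas: np.ndarray) -> BOLDDataset:
    """4D BOLD volume with HRF-convolved block responses in the active ROIs."""
    if tuple(roi_atlas.shape) != tuple(params.grid):
        raise ParameterError("atlas grid does not match params.grid")
    for label in params.active_rois:
        if not np.any(roi_atlas == label):
            raise ParameterError(f"ROI label {label} absent from atlas")
    reg = build_regressor(params.protocol, mode="hrf_convolved")  # peak-normalized
    n_t = reg.size
    rng = np.random.default_rng(params.seed)
    data = np.full(params.grid + (n_t,), params.baseline, dtype=np.float64)
    if params.noise_sd > 0:
        n_vox = int(np.prod(params.grid))
        noise = _ar1_noise(rng, n_t, n_vox, params.ar1_rho, params.noise_sd)
        data += noise.reshape(params.grid + (n_t,))
    for label, effect in params.active_rois.items():
        mask = roi_atlas == label
        data[mask] += effect * reg
    return BOLDDataset(data=data.astype(np.float32), tr=params.tr, protocol=params.protocol, atlas=roi_atlas)


# ---------------------------------------------------------------------------
# electrode placements
# ---------------------------------------------------------------------------


def generate_electrode_placements(
    n: int,
    target: tuple[float, float, float] = NACS_TARGET_MM,
    spread_mm: float = 0.4,
    effect_slope: float = -2.0,
    noise_sd: float = 0.66,
    intercept: float = -1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Electrode tips scattered around the target with a linear intake effect.

    delta-intake = intercept + effect_slope * distance + noise; the defaults
    are calibrated so the expected Spearman correlation between distance and
    delta-intake is ~ -0.6, the study's electrode-placement effect size.
    """
    if n < 3:
        raise ParameterError("need at least 3 placements")
    if spread_mm <= 0:
        raise ParameterError("spread_mm must be positive")
    rng = np.random.default_rng(seed)
    target = np.asarray(target, dtype=float)
    tips = target + spread_mm * rng.standard_normal((n, 3))
    dist = np.linalg.norm(tips - target, axis=1)
    delta = intercept + effect_slope * dist + noise_sd * rng.standard_normal(n)
    return pd.DataFrame(
        {
            "animal_id": [f"r{i + 1:02d}" for i in range(n)],
            "ap_mm": tips[:, 0],
            "ml_mm": tips[:, 1],
            "dv_mm": tips[:, 2],
            "distance_mm": dist,
            "delta_intake_g_per_kg": delta,
        }
    )


# ---------------------------------------------------------------------------
# tissue neurochemistry (post-mortem content tables)
# ---------------------------------------------------------------------------


def generate_tissue_content(
    n_per_cell: int = 6,
    baseline: float = 10.0,
    dependent_deficit: float = -2.5,
    dbs_effect_nondep: float = -2.0,
    dbs_effect_dep: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """NAc-shell dopamine tissue content with a programmed crossover interaction.

    Stimulation lowers dopamine in non-dependent animals but raises it in
    dependent animals (opposing regulation), on top of a dependence-related
    baseline deficit — the structure the factorial ANOVA must detect.
    """
    rng = np.random.default_rng(seed)
    rows = []
    idx = 0
    for stage in ("non_dependent", "dependent"):
        for stim in ("sham", "dbs"):
            mean = baseline
            if stage == "dependent":
                mean += dependent_deficit
            if stim == "dbs":
                mean += dbs_effect_dep if stage == "dependent" else dbs_effect_nondep
            vals = np.clip(mean + noise_sd * rng.standard_normal(n_per_cell), 0.0, None)
            for v in vals:
                idx += 1
                rows.append(
                    {
                        "animal_id": f"t{idx:02d}",
                        "stage": stage,
                        "stimulation": stim,
                        "region": "NAcs",
                        "analyte": "DA",
                        "value": float(v),
                    }
                )
    return pd.DataFrame(rows)
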