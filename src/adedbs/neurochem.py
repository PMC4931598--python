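"""Microdialysis dopamine series: baseline gating and percent-of-baseline.

Dialysate samples are collected every 20 min.  Before stimulation is switched
on, sampling continues until at least four consecutive stable values are
measured; the mean of the last four pre-stimulation samples defines the 100 %
baseline to which every sample is then referred.  After 60 min of stimulation
(or sham), three ascending alcohol doses (0.5, 1.0, 1.5 g/kg i.p. — the dose
unit follows the figure axis; an alternative mg/kg rendering in circulation
is treated as a typographical slip) are given at 40-min intervals.

The module also validates tidy post-mortem tissue-content tables
(region x analyte x dependence stage x stimulation) for the factorial ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError

SAMPLE_MINUTES = 20.0

STAGES = ("non_dependent", "dependent")
STIMULATIONS = ("sham", "dbs")
REGIONS = ("NAcs", "CPu", "mPFC")
ANALYTES = ("DA", "5HT", "Glu", "GABA")


@dataclass
class DialysateSeries:
    """Uniform 20-min dopamine samples around stimulation onset.

    ``dbs_on`` marks when stimulation starts (samples with ``t <= dbs_on``
    were collected before it); ``dose_times`` are the alcohol injections.
    ``units`` is an arbitrary concentration unit for raw data and
    ``"percent_baseline"`` after :func:`normalize_to_baseline`.
    """

    t: np.ndarray  # minutes
    da: np.ndarray
    dbs_on: float = 0.0
    dose_times: Sequence[float] = field(default_factory=tuple)
    doses_g_per_kg: Sequence[float] = field(default_factory=tuple)
    units: str = "a.u."

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.da = np.asarray(self.da, dtype=float)
        if self.t.shape != self.da.shape or self.t.ndim != 1:
            raise ParameterError("t and da must be 1-D arrays of equal length")
        if self.t.size >= 2 and not np.allclose(np.diff(self.t), SAMPLE_MINUTES):
            raise ParameterError("samples must be spaced exactly 20 min apart")

    @property
    def n_pre(self) -> int:
        return int(np.sum(self.t <= self.dbs_on))


def baseline_stable(series: DialysateSeries, k: int = 4, tol_cv: float = 0.15):
    """Whether the last ``k`` pre-stimulation samples are stable.

    Stability is a coefficient of variation (sample SD over mean) at most
    ``tol_cv`` over that window.  Returns ``(stable, window_values)``.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    pre = series.da[series.t <= series.dbs_on]
    if pre.size < k:
        raise ParameterError(f"need at least {k} pre-stimulation samples, have {pre.size}")
    window = pre[-k:]
    mean = window.mean()
    if mean == 0:
        return False, window
    sd = window.std(ddof=1) if k > 1 else 0.0
    return bool(sd / mean <= tol_cv), window


def normalize_to_baseline(series: DialysateSeries, k: int = 4) -> DialysateSeries:
    """Express the series relative to the pre-stimulation baseline (100 %).

    The baseline is the mean of the last ``k`` samples collected before
    stimulation started; the baseline-window mean of the output is exactly
    100.  Normalizing an already-normalized series is a no-op, and the
    transform is invariant to any positive rescaling of the raw data.
    """
    pre = series.da[series.t <= series.dbs_on]
    if pre.size < k:
        raise ParameterError(f"need at least {k} pre-stimulation samples, have {pre.size}")
    base = pre[-k:].mean()
    if base == 0:
        raise ParameterError("baseline mean is zero; cannot normalize")
    return replace(series, da=series.da / base * 100.0, units="percent_baseline")


def evoked_response_summary(series: DialysateSeries, dose_epoch_min: float = 40.0) -> pd.Series:
    """Mean percent-of-baseline per epoch: baseline, DBS-only, each dose.

    The DBS-only epoch runs from stimulation onset to the first alcohol dose;
    each dose epoch covers the ``dose_epoch_min`` minutes after its injection.
    Epochs without samples yield NaN.
    """
    if series.units != "percent_baseline":
        series = normalize_to_baseline(series)
    t, da = series.t, series.da
    out: dict[str, float] = {}
    pre = da[t <= series.dbs_on][-4:]
    out["baseline"] = float(pre.mean()) if pre.size else float("nan")
    first_dose = min(series.dose_times) if len(series.dose_times) else t[-1] + SAMPLE_MINUTES
    sel = (t > series.dbs_on) & (t <= first_dose)
    out["dbs"] = float(da[sel].mean()) if sel.any() else float("nan")
    for i, t0 in enumerate(sorted(series.dose_times)):
        sel = (t > t0) & (t <= t0 + dose_epoch_min)
        label = f"dose{i + 1}"
        if i < len(series.doses_g_per_kg):
            label = f"dose_{series.doses_g_per_kg[i]:g}g_per_kg"
        out[label] = float(da[sel].mean()) if sel.any() else float("nan")
    return pd.Series(out)


def assemble_tissue_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a tidy tissue-content table for the factorial analysis.

    Required columns: animal_id, stage, stimulation, region, analyte, value;
    values must be non-negative, labels drawn from the study's factor levels.
    """
    required = {"animal_id", "stage", "stimulation", "region", "analyte", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterError(f"missing columns: {sorted(missing)}")
    if (df["value"] < 0).any():
        raise ParameterError("tissue contents must be non-negative")
    for col, levels in (("stage", STAGES), ("stimulation", STIMULATIONS),
                        ("region", REGIONS), ("analyte", ANALYTES)):
        bad = set(df[col]) - set(levels)
        if bad:
            raise ParameterError(f"unknown {col} labels: {sorted(bad)}")
    return df.reset_index(drop=True)
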