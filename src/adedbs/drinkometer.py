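"""Drinking-microstructure analysis of multi-bottle drinkometer recordings.

A drinkometer weighs the liquid removed from each of four bottles (water and
5/10/20 % v/v ethanol) in 5-min bins.  Relapse-like drinking after an alcohol
deprivation phase (the alcohol-deprivation effect, ADE) changes both how often
an animal approaches the ethanol bottles and how much it drinks per approach.
This module quantifies those two aspects with a truncated Fourier description
of the intake series:

* frequency of maximal intake peaks per hour  — incentive salience, "wanting";
* mean height of those peaks per 5-min bin    — hedonic impact, "liking".

All ethanol metrics are expressed in grams of pure ethanol per kilogram of
body weight, water metrics in millilitres per kilogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError

BIN_MINUTES = 5.0
BINS_PER_DAY = int(24 * 60 / BIN_MINUTES)  # 288

#: bottles of the four-bottle free-choice paradigm, in canonical order
BOTTLES = ("water", "etoh5", "etoh10", "etoh20")

#: nominal ethanol concentration of each bottle, % v/v
CONCENTRATION = {"water": 0.0, "etoh5": 5.0, "etoh10": 10.0, "etoh20": 20.0}

#: density of pure ethanol, g/ml; the solution itself is weighed as ~1 g/ml
ETHANOL_DENSITY_G_PER_ML = 0.789


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class DrinkometerSeries:
    """Per-bottle intake series sampled in uniform 5-min bins.

    ``y`` holds grams of liquid removed per bin for raw recordings
    (``units == "g"``) or dose units after :func:`to_dose_units`
    (``"g/kg"`` for ethanol, ``"ml/kg"`` for water).
    """

    animal_id: str
    bottle: str
    t: np.ndarray  # minutes since recording start, uniform 5-min steps
    y: np.ndarray  # intake per bin
    body_weight: float  # grams
    units: str = "g"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.bottle not in BOTTLES:
            raise ParameterError(f"unknown bottle {self.bottle!r}")
        if self.t.shape != self.y.shape or self.t.ndim != 1:
            raise ParameterError("t and y must be 1-D arrays of equal length")
        if self.t.size >= 2 and not np.allclose(np.diff(self.t), BIN_MINUTES):
            raise ParameterError("samples must be spaced exactly 5 min apart")
        if np.any(self.y < 0):
            raise ParameterError("intake per bin cannot be negative")
        if self.body_weight <= 0:
            raise ParameterError("body weight must be positive")

    @property
    def L(self) -> float:
        """Length of the measurement interval in minutes (bin-inclusive)."""
        return float(self.t[-1] - self.t[0] + BIN_MINUTES)

    @property
    def n_days(self) -> int:
        return int(self.t.size // BINS_PER_DAY)


@dataclass
class FourierModel:
    """Truncated real Fourier series fitted to one bottle's series.

    y(t) ~ a0 + sum_k a_k cos(2 pi nu_k tau) + b_k sin(2 pi nu_k tau),
    with tau = t - t0, nu_k = k / L, k = 1..K.
    """

    a0: float
    a: np.ndarray  # a_k, k = 1..K
    b: np.ndarray  # b_k, k = 1..K
    L: float  # minutes
    t0: float  # minutes, grid origin
    n_samples: int
    bottle: str
    units: str

    @property
    def K(self) -> int:
        return int(self.a.size)

    @property
    def nu(self) -> np.ndarray:
        """Frequencies nu_k = k / L in cycles per minute, strictly increasing."""
        return np.arange(1, self.K + 1) / self.L

    def reconstruct(self, t: np.ndarray | None = None) -> np.ndarray:
        """Evaluate the truncated series; on the native grid uses the inverse DFT."""
        if t is None:
            # exact inverse transform on the original uniform grid
            n = self.n_samples
            spec = np.zeros(n // 2 + 1, dtype=complex)
            spec[0] = self.a0 * n
            k = np.arange(1, self.K + 1)
            half = (n % 2 == 0) & (k == n // 2)
            scale = np.where(half, 1.0, 0.5)
            spec[1 : self.K + 1] = (self.a - 1j * self.b) * scale * n
            return np.fft.irfft(spec, n)
        tau = np.asarray(t, dtype=float) - self.t0
        k = np.arange(1, self.K + 1)
        ang = 2 * np.pi * np.outer(tau, k) / self.L
        return self.a0 + ang_cos_sin(ang, self.a, self.b)


def ang_cos_sin(ang: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.cos(ang) @ a + np.sin(ang) @ b


@dataclass
class DrinkingPatternMetrics:
    """Peak-based summary of a fitted drinking pattern.

    amplitude  mean maximal-peak intake per 5-min bin (ml/kg water, g/kg ethanol)
    frequency  maximal-intake-peak occurrences per hour
    peak_times minutes (within the fitted interval)
    """

    amplitude: float
    frequency: float
    peak_times: np.ndarray = field(default_factory=lambda: np.array([]))
    peak_heights: np.ndarray = field(default_factory=lambda: np.array([]))
    threshold: float = 0.2


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def to_dose_units(series: DrinkometerSeries, concentration: float | None = None) -> DrinkometerSeries:
    """Convert grams of liquid removed to g ethanol/kg (ethanol) or ml/kg (water).

    Ethanol: grams liquid -> ml solution (density ~1 g/ml) -> ml ethanol
    (x c/100) -> g ethanol (x 0.789) -> per kg body weight.
    Water: grams -> ml -> per kg body weight.
    """
    if series.units != "g":
        raise ParameterError(f"series already in dose units ({series.units})")
    if concentration is None:
        concentration = CONCENTRATION[series.bottle]
    if concentration not in (0, 5, 10, 20):
        raise ParameterError(f"concentration must be one of 0/5/10/20 %v/v, got {concentration}")
    bw_kg = series.body_weight / 1000.0
    if bw_kg <= 0:
        raise ParameterError("body weight must be positive")
    ml = series.y / 1.0  # solution density approximated as 1 g/ml
    if concentration == 0:
        y = ml / bw_kg
        units = "ml/kg"
    else:
        g_ethanol = ml * (concentration / 100.0) * ETHANOL_DENSITY_G_PER_ML
        y = g_ethanol / bw_kg
        units = "g/kg"
    return replace(series, y=y, units=units)


def fit_fourier(series: DrinkometerSeries, K: int | None = None) -> FourierModel:
    """Least-squares truncated real Fourier series on the uniform 5-min grid.

    On a uniform grid the least-squares fit coincides with the (truncated)
    discrete Fourier transform, which is how the coefficients are computed.
    ``K=None`` keeps every resolvable harmonic (K = N//2), so the
    reconstruction interpolates the data; smaller K low-pass filters it.
    """
    y = series.y
    n = y.size
    if n < 2:
        raise ParameterError("need at least 2 samples")
    if K is None:
        K = n // 2
    K = int(K)
    if K < 0 or K > n // 2:
        raise ParameterError(f"K={K} out of range for {n} samples (max {n // 2})")
    spec = np.fft.rfft(y)
    a0 = float(spec[0].real) / n
    k = np.arange(1, K + 1)
    a = 2.0 * spec[1 : K + 1].real / n
    b = -2.0 * spec[1 : K + 1].imag / n
    if n % 2 == 0 and K == n // 2:
        # Nyquist harmonic carries no factor 2 and no sine partner
        a[-1] *= 0.5
        b[-1] = 0.0
    return FourierModel(
        a0=a0, a=a, b=b, L=series.L, t0=float(series.t[0]),
        n_samples=n, bottle=series.bottle, units=series.units,
    )


def _run_length_peaks(r: np.ndarray) -> np.ndarray:
    """Indices of local maxima of ``r``; plateaus count once, earliest bin wins."""
    n = r.size
    if n == 0:
        return np.array([], dtype=int)
    # run-length encode
    change = np.flatnonzero(np.diff(r) != 0) + 1
    starts = np.concatenate(([0], change))
    vals = r[starts]
    peaks = []
    for j, s in enumerate(starts):
        left_ok = j == 0 or vals[j - 1] < vals[j]
        right_ok = j == len(starts) - 1 or vals[j + 1] < vals[j]
        if left_ok and right_ok:
            peaks.append(s)
    return np.asarray(peaks, dtype=int)


def extract_pattern_metrics(model: FourierModel, peak_threshold: float = 0.2) -> DrinkingPatternMetrics:
    """Peak metrics from the reconstructed pattern.

    Peaks are local maxima of the reconstruction on the native 5-min grid that
    are positive and reach ``peak_threshold`` x the global maximum (the
    threshold suppresses Gibbs ripples around discrete bouts).  amplitude is
    the mean peak height; frequency the peak count per hour of record.
    """
    if not 0 <= peak_threshold <= 1:
        raise ParameterError("peak_threshold must be a fraction in [0, 1]")
    r = model.reconstruct()
    top = float(r.max(initial=0.0))
    if top <= 0:
        return DrinkingPatternMetrics(0.0, 0.0, threshold=peak_threshold)
    idx = _run_length_peaks(r)
    keep = (r[idx] >= peak_threshold * top) & (r[idx] > 0)
    idx = idx[keep]
    heights = r[idx]
    hours = model.L / 60.0
    times = model.t0 + idx * BIN_MINUTES
    amplitude = float(heights.mean()) if heights.size else 0.0
    return DrinkingPatternMetrics(
        amplitude=amplitude,
        frequency=float(heights.size / hours),
        peak_times=times,
        peak_heights=heights,
        threshold=peak_threshold,
    )


def fold_change(value_a: float, value_b: float) -> float:
    """Ratio value_a / value_b (e.g. ADE day 1 over baseline)."""
    if value_b == 0:
        raise ParameterError("fold change undefined for zero reference value")
    return float(value_a) / float(value_b)


def daily_totals(series_list: Iterable[DrinkometerSeries]) -> pd.DataFrame:
    """Per-day ethanol (g/kg/day) and water (ml/kg/day) totals per animal.

    Raw (grams) series are converted to dose units first.  A partial trailing
    day is excluded with a warning.  The result feeds the repeated-measures
    ANOVA of total daily intake.
    """
    rows = []
    for s in series_list:
        if s.units == "g":
            s = to_dose_units(s)
        n_full = s.y.size // BINS_PER_DAY
        if s.y.size % BINS_PER_DAY:
            warnings.warn(
                f"{s.animal_id}/{s.bottle}: partial trailing day excluded from daily totals",
                stacklevel=2,
            )
        if n_full == 0:
            continue
        per_day = s.y[: n_full * BINS_PER_DAY].reshape(n_full, BINS_PER_DAY).sum(axis=1)
        for d, v in enumerate(per_day):
            rows.append(
                {
                    "animal_id": s.animal_id,
                    "day": d,
                    "bottle": s.bottle,
                    "kind": "water" if s.bottle == "water" else "ethanol",
                    "total": float(v),
                    "units": s.units + "/day",
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["animal_id", "day", "ethanol_g_per_kg", "water_ml_per_kg"])
    wide = (
        df.pivot_table(index=["animal_id", "day"], columns="kind", values="total", aggfunc="sum")
        .rename(columns={"ethanol": "ethanol_g_per_kg", "water": "water_ml_per_kg"})
        .reset_index()
    )
    for col in ("ethanol_g_per_kg", "water_ml_per_kg"):
        if col not in wide:
            wide[col] = 0.0
    wide.columns.name = None
    return wide


# ---------------------------------------------------------------------------
# cohort-level relapse analysis (Table-1-style rows)
# ---------------------------------------------------------------------------


def metrics_per_day(
    series: DrinkometerSeries,
    days: Sequence[int],
    K: int | None = None,
    peak_threshold: float = 0.2,
) -> list[DrinkingPatternMetrics]:
    """Fit and summarize each listed calendar day of one dose-unit series."""
    if series.units == "g":
        series = to_dose_units(series)
    out = []
    for d in days:
        sl = slice(d * BINS_PER_DAY, (d + 1) * BINS_PER_DAY)
        if (d + 1) * BINS_PER_DAY > series.y.size:
            raise ParameterError(f"day {d} not fully covered by the recording")
        day_series = replace(series, t=series.t[sl], y=series.y[sl])
        out.append(extract_pattern_metrics(fit_fourier(day_series, K=K), peak_threshold))
    return out


def relapse_pattern_summary(
    members: Iterable,
    ade_day: int,
    baseline_days: int = 6,
    K: int | None = None,
    peak_threshold: float = 0.2,
) -> pd.DataFrame:
    """Amplitude/frequency per animal, bottle and relapse window.

    Windows follow the study layout: ``baseline`` averages per-day metrics over
    the last ``baseline_days`` days before deprivation, ``ade1`` is the first
    post-abstinence day and ``ade2_4`` the mean of the following three days.
    ``members`` are objects with ``animal_id``, ``group`` and a
    ``series`` mapping bottle -> :class:`DrinkometerSeries`.
    """
    windows = {
        "baseline": list(range(ade_day - baseline_days, ade_day)),
        "ade1": [ade_day],
        "ade2_4": [ade_day + 1, ade_day + 2, ade_day + 3],
    }
    rows = []
    for m in members:
        for bottle in BOTTLES:
            if bottle not in m.series:
                continue
            s = m.series[bottle]
            for window, days in windows.items():
                ms = metrics_per_day(s, days, K=K, peak_threshold=peak_threshold)
                rows.append(
                    {
                        "animal_id": m.animal_id,
                        "group": m.group,
                        "bottle": bottle,
                        "window": window,
                        "amplitude": float(np.mean([x.amplitude for x in ms])),
                        "frequency": float(np.mean([x.frequency for x in ms])),
                    }
                )
    return pd.DataFrame(rows)


def pattern_fold_changes(summary: pd.DataFrame) -> pd.DataFrame:
    """Group-mean fold changes of amplitude/frequency over baseline.

    One row per (group, bottle, window in {ade1, ade2_4}); baseline refers to
    the same group's mean baseline metric.
    """
    g = summary.groupby(["group", "bottle", "window"])[["amplitude", "frequency"]].mean()
    rows = []
    for (group, bottle), sub in g.groupby(level=["group", "bottle"]):
        sub = sub.droplevel(["group", "bottle"])
        base = sub.loc["baseline"]
        for window in ("ade1", "ade2_4"):
            if window not in sub.index:
                continue
            rows.append(
                {
                    "group": group,
                    "bottle": bottle,
                    "window": window,
                    "amplitude_fold": fold_change(sub.loc[window, "amplitude"], base["amplitude"])
                    if base["amplitude"] > 0
                    else np.nan,
                    "frequency_fold": fold_change(sub.loc[window, "frequency"], base["frequency"])
                    if base["frequency"] > 0
                    else np.nan,
                }
            )
    return pd.DataFrame(rows)
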