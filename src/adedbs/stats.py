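"""Inferential layer: mixed-design ANOVA, SNK post hoc, Spearman, distances.

The study's designs map onto:

* two-way repeated-measures ANOVA — between factor stimulation (sham vs DBS),
  within factor time (baseline vs post-abstinence days), error terms
  subjects-within-group (between) and time x subjects-within-group (within);
* Student-Newman-Keuls stepwise studentized-range post hoc after a
  significant ANOVA;
* two-way factorial ANOVA for tissue neurochemistry (dependence stage x
  stimulation);
* tie-corrected Spearman rank correlation (electrode distance vs intake
  change) and Euclidean stereotaxic distance to the implantation target.

Sums of squares are computed from first principles; studentized-range
quantiles come from the numerically integrated range distribution rather
than printed tables.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DesignError, ParameterError


# ---------------------------------------------------------------------------
# two-way repeated-measures (mixed) ANOVA
# ---------------------------------------------------------------------------


def _rm_anova_core(y: np.ndarray) -> dict[str, dict[str, float]]:
    """Mixed ANOVA on a balanced (groups a, subjects n, times b) array."""
    a, n, b = y.shape
    if a < 2 or b < 2 or n < 2:
        raise DesignError("need >= 2 groups, >= 2 subjects per group and >= 2 time levels")
    grand = y.mean()
    subj = y.mean(axis=2)
    group = y.mean(axis=(1, 2))
    time = y.mean(axis=(0, 1))
    cell = y.mean(axis=1)
    ss_total = float(((y - grand) ** 2).sum())
    ss_subjects = float(b * ((subj - grand) ** 2).sum())
    ss_group = float(n * b * ((group - grand) ** 2).sum())
    ss_subj_within = ss_subjects - ss_group
    ss_time = float(a * n * ((time - grand) ** 2).sum())
    ss_inter = float(
        n * ((cell - group[:, None] - time[None, :] + grand) ** 2).sum()
    )
    ss_error = ss_total - ss_subjects - ss_time - ss_inter
    df_group, df_sw = a - 1, a * (n - 1)
    df_time = b - 1
    df_inter = (a - 1) * (b - 1)
    df_error = a * (n - 1) * (b - 1)

    def effect(ss, df, ss_err, df_err):
        ms, ms_err = ss / df, ss_err / df_err
        if ms_err <= 0:
            return {"ss": ss, "df": df, "ms": ms, "F": 0.0, "p": 1.0,
                    "ss_error": ss_err, "df_error": df_err, "note": "zero error variance"}
        F = ms / ms_err
        return {"ss": ss, "df": df, "ms": ms, "F": F,
                "p": float(sps.f.sf(F, df, df_err)),
                "ss_error": ss_err, "df_error": df_err, "note": ""}

    return {
        "group": effect(ss_group, df_group, ss_subj_within, df_sw),
        "time": effect(ss_time, df_time, ss_error, df_error),
        "group:time": effect(ss_inter, df_inter, ss_error, df_error),
        "_totals": {"ss_total": ss_total, "ss_subj_within": ss_subj_within,
                    "ss_error": ss_error},
    }


def rm_anova_two_way(
    df: pd.DataFrame,
    subject: str = "subject",
    between: str = "group",
    within: str = "time",
    response: str = "value",
) -> pd.DataFrame:
    """Two-way mixed ANOVA: between-subject group, within-subject time.

    Requires a balanced complete design (every subject observed once per
    time level, equal group sizes); missing cells raise rather than impute.
    Returns one row per effect with SS, df, F and p.
    """
    groups = sorted(df[between].unique())
    times = sorted(df[within].unique())
    counts = df.groupby([subject, within]).size()
    if (counts != 1).any():
        raise DesignError("each subject needs exactly one observation per time level")
    subj_group = df.groupby(subject)[between].nunique()
    if (subj_group != 1).any():
        raise DesignError("each subject must belong to exactly one group")
    n_per = df.groupby(between)[subject].nunique()
    if n_per.nunique() != 1:
        raise DesignError("unbalanced design: unequal group sizes")
    n = int(n_per.iloc[0])
    a, b = len(groups), len(times)
    y = np.empty((a, n, b))
    for gi, g in enumerate(groups):
        sub = df[df[between] == g]
        subjects = sorted(sub[subject].unique())
        pivot = sub.pivot(index=subject, columns=within, values=response).loc[subjects, times]
        if pivot.isna().any().any():
            raise DesignError("missing cells in the design")
        y[gi] = pivot.to_numpy()
    res = _rm_anova_core(y)
    rows = []
    for name in ("group", "time", "group:time"):
        e = res[name]
        rows.append({"effect": name, **{k: e[k] for k in
                     ("ss", "df", "ms", "F", "p", "df_error", "note")}})
    return pd.DataFrame(rows)


def simulate_rm_anova_type1(
    n_rep: int = 5000,
    n_groups: int = 2,
    n_subjects: int = 8,
    n_times: int = 4,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Empirical type-I error per factor under the global null (iid noise)."""
    rng = np.random.default_rng(seed)
    hits = {"group": 0, "time": 0, "group:time": 0}
    for _ in range(n_rep):
        y = rng.standard_normal((n_groups, n_subjects, n_times))
        res = _rm_anova_core(y)
        for k in hits:
            if res[k]["p"] < alpha:
                hits[k] += 1
    return {k: v / n_rep for k, v in hits.items()}


# ---------------------------------------------------------------------------
# Student-Newman-Keuls post hoc
# ---------------------------------------------------------------------------


def snk_posthoc(
    cell_means: Mapping[str, float],
    ms_error: float,
    df_error: int,
    n_per_cell: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Stepwise studentized-range comparisons of sorted cell means.

    The critical value depends on the number of means spanned; once a span
    is declared non-significant, every pair inside it is non-significant
    without testing (standard SNK coherence).
    """
    if n_per_cell < 2:
        raise ParameterError("n_per_cell must be >= 2")
    if ms_error < 0 or df_error < 1:
        raise ParameterError("invalid error term")
    names = sorted(cell_means, key=lambda k: cell_means[k], reverse=True)
    means = np.array([cell_means[k] for k in names])
    k = len(names)
    se = np.sqrt(ms_error / n_per_cell)
    blocked: list[tuple[int, int]] = []
    rows = []
    for span in range(k, 1, -1):
        q_crit = float(sps.studentized_range.ppf(1 - alpha, span, df_error))
        for i in range(0, k - span + 1):
            j = i + span - 1
            inside_block = any(bi <= i and j <= bj for bi, bj in blocked)
            diff = means[i] - means[j]
            q = diff / se if se > 0 else (np.inf if diff > 0 else 0.0)
            sig = (not inside_block) and q > q_crit
            if not sig and not inside_block:
                blocked.append((i, j))
            rows.append(
                {
                    "a": names[i],
                    "b": names[j],
                    "diff": float(diff),
                    "span": span,
                    "q": float(q) if np.isfinite(q) else np.inf,
                    "q_crit": q_crit,
                    "significant": bool(sig),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# two-way factorial ANOVA (tissue tables)
# ---------------------------------------------------------------------------


def _design(levels_a: np.ndarray, levels_b: np.ndarray, include: set[str]) -> np.ndarray:
    """Sum-to-zero-coded design matrix with the requested terms."""
    a_lev = np.unique(levels_a)
    b_lev = np.unique(levels_b)
    cols = [np.ones(levels_a.size)]
    a_cols, b_cols = [], []
    for lev in a_lev[:-1]:
        c = (levels_a == lev).astype(float) - (levels_a == a_lev[-1]).astype(float)
        a_cols.append(c)
    for lev in b_lev[:-1]:
        c = (levels_b == lev).astype(float) - (levels_b == b_lev[-1]).astype(float)
        b_cols.append(c)
    if "a" in include:
        cols += a_cols
    if "b" in include:
        cols += b_cols
    if "ab" in include:
        cols += [ca * cb for ca, cb in itertools.product(a_cols, b_cols)]
    return np.column_stack(cols)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def anova_two_way_factorial(
    df: pd.DataFrame,
    factor_a: str = "stage",
    factor_b: str = "stimulation",
    response: str = "value",
) -> pd.DataFrame:
    """Two-way factorial ANOVA with interaction (between-subject only).

    Effect sums of squares are computed by model comparison with sum-to-zero
    coding (Type III, which reduces to the classical decomposition when the
    design is balanced).  Every cell needs at least 2 observations.
    """
    la = df[factor_a].to_numpy()
    lb = df[factor_b].to_numpy()
    y = df[response].to_numpy(dtype=float)
    cells = df.groupby([factor_a, factor_b]).size()
    n_a, n_b = len(np.unique(la)), len(np.unique(lb))
    if len(cells) < n_a * n_b:
        raise DesignError("empty cell in the factorial design")
    if (cells < 2).any():
        raise DesignError("need >= 2 observations per cell")
    full = _design(la, lb, {"a", "b", "ab"})
    rss_full = _rss(full, y)
    df_resid = y.size - full.shape[1]
    rows = []
    for name, dropped, df_eff in (
        (factor_a, {"b", "ab"}, n_a - 1),
        (factor_b, {"a", "ab"}, n_b - 1),
        (f"{factor_a}:{factor_b}", {"a", "b"}, (n_a - 1) * (n_b - 1)),
    ):
        ss = _rss(_design(la, lb, dropped), y) - rss_full
        ss = max(ss, 0.0)
        ms_err = rss_full / df_resid
        if ms_err <= 0:
            F, p, note = 0.0, 1.0, "zero error variance"
        else:
            F = (ss / df_eff) / ms_err
            p, note = float(sps.f.sf(F, df_eff, df_resid)), ""
        rows.append({"effect": name, "ss": ss, "df": df_eff, "F": F, "p": p,
                     "df_error": df_resid, "note": note})
    rows.append({"effect": "residual", "ss": rss_full, "df": df_resid,
                 "F": np.nan, "p": np.nan, "df_error": df_resid, "note": ""})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Spearman correlation and electrode distances
# ---------------------------------------------------------------------------


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Tie-corrected Spearman correlation: Pearson correlation of mid-ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ParameterError("x and y must have equal length")
    if x.size < 3:
        raise ParameterError("need at least 3 paired observations")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        warnings.warn("zero variance in ranks; Spearman rho undefined", stacklevel=2)
        return float("nan")
    return float((rx @ ry) / denom)


def distance_to_target(
    tip: Sequence[float], target: Sequence[float] = (1.6, 0.8, 7.6)
) -> float:
    """Euclidean distance (mm) between an electrode tip and the target.

    Coordinates are stereotaxic (AP, ML, DV).  If the ML signs disagree the
    tip is reflected into the target hemisphere first, with a warning.
    """
    tip = np.asarray(tip, dtype=float)
    target = np.asarray(target, dtype=float)
    if tip.shape != (3,) or target.shape != (3,):
        raise ParameterError("tip and target must be (AP, ML, DV) triples")
    if not (np.isfinite(tip).all() and np.isfinite(target).all()):
        raise ParameterError("coordinates must be finite")
    if tip[1] * target[1] < 0:
        warnings.warn("tip and target in opposite hemispheres; reflecting ML", stacklevel=2)
        tip = tip.copy()
        tip[1] = -tip[1]
    return float(np.linalg.norm(tip - target))


def placement_correlation(placements: pd.DataFrame) -> float:
    """Spearman rho between electrode distance-to-target and intake change."""
    return spearman_rho(
        placements["distance_mm"].to_numpy(),
        placements["delta_intake_g_per_kg"].to_numpy(),
    )
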