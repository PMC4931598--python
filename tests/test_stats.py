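"""ANOVA machinery, SNK stepwise logic, Spearman and stereotaxic distances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as sps

from adedbs import simulate as sim
from adedbs import stats as st
from adedbs.errors import DesignError, ParameterError


def rm_frame(y):
    """Long-format frame from a (groups, subjects, times) array."""
    a, n, b = y.shape
    rows = []
    for gi in range(a):
        for si in range(n):
            for ti in range(b):
                rows.append(
                    {"subject": f"g{gi}s{si}", "group": f"g{gi}", "time": ti,
                     "value": y[gi, si, ti]}
                )
    return pd.DataFrame(rows)


def rm_anova_oracle(y):
    """Brute-force sums-of-squares mixed ANOVA written with plain loops."""
    a, n, b = y.shape
    grand = y.mean()
    ss_group = sum(n * b * (y[g].mean() - grand) ** 2 for g in range(a))
    ss_subj = sum(b * (y[g, s].mean() - grand) ** 2 for g in range(a) for s in range(n))
    ss_time = sum(a * n * (y[:, :, t].mean() - grand) ** 2 for t in range(b))
    ss_cell = sum(
        n * (y[g, :, t].mean() - y[g].mean() - y[:, :, t].mean() + grand) ** 2
        for g in range(a)
        for t in range(b)
    )
    ss_total = float(((y - grand) ** 2).sum())
    ss_sw = ss_subj - ss_group
    ss_err = ss_total - ss_subj - ss_time - ss_cell
    f_group = (ss_group / (a - 1)) / (ss_sw / (a * (n - 1)))
    f_time = (ss_time / (b - 1)) / (ss_err / (a * (n - 1) * (b - 1)))
    f_inter = (ss_cell / ((a - 1) * (b - 1))) / (ss_err / (a * (n - 1) * (b - 1)))
    return f_group, f_time, f_inter, ss_total, (ss_group, ss_sw, ss_time, ss_cell, ss_err)


class TestRmAnova:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        y = rng.normal(size=(2, 5, 3)) + np.arange(3) * 0.4
        res = st.rm_anova_two_way(rm_frame(y)).set_index("effect")
        f_group, f_time, f_inter, *_ = rm_anova_oracle(y)
        assert res.loc["group", "F"] == pytest.approx(f_group, abs=1e-10)
        assert res.loc["time", "F"] == pytest.approx(f_time, abs=1e-10)
        assert res.loc["group:time", "F"] == pytest.approx(f_inter, abs=1e-10)

    def test_sums_of_squares_additive(self):
        rng = np.random.default_rng(21)
        y = rng.normal(size=(2, 6, 4))
        *_, ss_total, parts = rm_anova_oracle(y)
        core = st._rm_anova_core(y)
        ss_sum = (
            core["group"]["ss"]
            + core["time"]["ss"]
            + core["group:time"]["ss"]
            + core["_totals"]["ss_subj_within"]
            + core["_totals"]["ss_error"]
        )
        assert ss_sum == pytest.approx(ss_total, rel=1e-9)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        y = rng.normal(size=(2, 6, 4)) + np.arange(4) * 0.3
        df = rm_frame(y)
        mine = st.rm_anova_two_way(df).set_index("effect")
        ref = pg.mixed_anova(df, dv="value", within="time", subject="subject",
                             between="group").set_index("Source")
        assert mine.loc["group", "F"] == pytest.approx(ref.loc["group", "F"], rel=1e-9)
        assert mine.loc["time", "F"] == pytest.approx(ref.loc["time", "F"], rel=1e-9)
        assert mine.loc["group:time", "F"] == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-9
        )

    def test_identical_responses_give_zero_f_with_note(self):
        y = np.full((2, 4, 3), 2.0)
        res = st.rm_anova_two_way(rm_frame(y))
        assert np.all(res["F"] == 0.0)
        assert (res["note"] == "zero error variance").all()

    def test_missing_cell_rejected(self):
        df = rm_frame(np.zeros((2, 4, 3))).iloc[:-1]
        with pytest.raises(DesignError):
            st.rm_anova_two_way(df)

    def test_unbalanced_groups_rejected(self):
        df = rm_frame(np.zeros((2, 4, 3)))
        df = df[df["subject"] != "g1s3"]
        with pytest.raises(DesignError):
            st.rm_anova_two_way(df)

    def test_type_one_error_calibrated(self):
        rates = st.simulate_rm_anova_type1(n_rep=1200, seed=31)
        se = np.sqrt(0.05 * 0.95 / 1200)
        for factor, rate in rates.items():
            assert abs(rate - 0.05) <= 3.5 * se, factor


class TestSnk:
    def test_equal_means_not_significant(self):
        out = st.snk_posthoc({"a": 1.0, "b": 1.0}, 0.5, 12, 5)
        assert not out["significant"].any()

    def test_outlier_detected_inner_pair_follows_q_table(self):
        # published 5 % studentized-range points: q(2,12)=3.08, q(3,12)=3.77
        out = st.snk_posthoc({"a": 0.0, "b": 0.1, "c": 5.0}, 0.5, 12, 5).set_index(["a", "b"])
        assert out.loc[("c", "a"), "significant"]
        assert out.loc[("c", "b"), "significant"]
        assert not out.loc[("b", "a"), "significant"]
        assert out.loc[("c", "a"), "q_crit"] == pytest.approx(3.77, abs=0.01)
        assert out.loc[("b", "a"), "q_crit"] == pytest.approx(3.08, abs=0.01)

    def test_alpha_near_one_flags_all_distinct_pairs(self):
        out = st.snk_posthoc({"a": 0.0, "b": 1.0, "c": 2.0}, 0.5, 12, 5, alpha=0.9999)
        assert out["significant"].all()

    def test_coherence_no_inner_pair_inside_nonsignificant_span(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            means = {f"m{i}": float(v) for i, v in enumerate(rng.normal(0, 1, 5))}
            out = st.snk_posthoc(means, ms_error=2.0, df_error=20, n_per_cell=4)
            order = sorted(means, key=means.get, reverse=True)
            pos = {k: i for i, k in enumerate(order)}
            ns_spans = [
                (pos[r.a], pos[r.b]) for r in out.itertuples() if not r.significant
            ]
            for r in out.itertuples():
                if r.significant:
                    assert not any(
                        lo <= pos[r.a] and pos[r.b] <= hi for lo, hi in ns_spans
                        if (lo, hi) != (pos[r.a], pos[r.b])
                        and (pos[r.b] - pos[r.a]) < (hi - lo)
                    )

    def test_small_cells_rejected(self):
        with pytest.raises(ParameterError):
            st.snk_posthoc({"a": 0.0, "b": 1.0}, 0.5, 12, 1)


def factorial_oracle(df):
    """Classical balanced two-way SS decomposition with plain loops."""
    grand = df["value"].mean()
    ss = {}
    ga = df.groupby("stage")["value"]
    gb = df.groupby("stimulation")["value"]
    cells = df.groupby(["stage", "stimulation"])["value"]
    n_cell = cells.size().iloc[0]
    n_b = df["stimulation"].nunique()
    n_a = df["stage"].nunique()
    ss["a"] = sum(len(v) * (v.mean() - grand) ** 2 for _, v in ga)
    ss["b"] = sum(len(v) * (v.mean() - grand) ** 2 for _, v in gb)
    ss["cells"] = sum(len(v) * (v.mean() - grand) ** 2 for _, v in cells)
    ss["ab"] = ss["cells"] - ss["a"] - ss["b"]
    ss["resid"] = sum(((v - v.mean()) ** 2).sum() for _, v in cells)
    df_resid = len(df) - n_a * n_b
    return ss, df_resid


class TestFactorialAnova:
    def test_matches_hand_computed_oracle_on_balanced_table(self):
        df = sim.generate_tissue_content(n_per_cell=5, seed=9)
        res = st.anova_two_way_factorial(df).set_index("effect")
        ss, df_resid = factorial_oracle(df)
        assert res.loc["stage", "ss"] == pytest.approx(ss["a"], abs=1e-10)
        assert res.loc["stimulation", "ss"] == pytest.approx(ss["b"], abs=1e-10)
        assert res.loc["stage:stimulation", "ss"] == pytest.approx(ss["ab"], abs=1e-10)
        assert res.loc["residual", "ss"] == pytest.approx(ss["resid"], abs=1e-10)
        assert res.loc["residual", "df"] == df_resid

    def test_sums_of_squares_additive_when_balanced(self):
        df = sim.generate_tissue_content(n_per_cell=4, seed=2)
        res = st.anova_two_way_factorial(df)
        total = ((df["value"] - df["value"].mean()) ** 2).sum()
        assert res["ss"].sum() == pytest.approx(total, rel=1e-9)

    def test_matches_statsmodels_type3(self):
        smf = pytest.importorskip("statsmodels.formula.api")
        import statsmodels.api as sm

        df = sim.generate_tissue_content(n_per_cell=6, seed=4)
        mine = st.anova_two_way_factorial(df).set_index("effect")
        fit = smf.ols("value ~ C(stage, Sum)*C(stimulation, Sum)", data=df).fit()
        ref = sm.stats.anova_lm(fit, typ=3)
        assert mine.loc["stage", "F"] == pytest.approx(ref.loc["C(stage, Sum)", "F"], rel=1e-8)
        assert mine.loc["stage:stimulation", "F"] == pytest.approx(
            ref.loc["C(stage, Sum):C(stimulation, Sum)", "F"], rel=1e-8
        )

    def test_identical_values_give_zero_f(self):
        df = sim.generate_tissue_content(noise_sd=0.0, dependent_deficit=0.0,
                                         dbs_effect_nondep=0.0, dbs_effect_dep=0.0, seed=0)
        res = st.anova_two_way_factorial(df)
        assert np.all(res["F"].iloc[:3] == 0.0)

    def test_empty_cell_rejected(self):
        df = sim.generate_tissue_content(seed=1)
        df = df[~((df.stage == "dependent") & (df.stimulation == "dbs"))]
        with pytest.raises(DesignError):
            st.anova_two_way_factorial(df)

    def test_programmed_crossover_interaction_detected_with_power(self):
        hits = 0
        reps = 40
        for s in range(reps):
            df = sim.generate_tissue_content(seed=1000 + s)
            res = st.anova_two_way_factorial(df).set_index("effect")
            hits += res.loc["stage:stimulation", "p"] < 0.05
        assert hits / reps >= 0.8


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert st.spearman_rho(x, x**3) == pytest.approx(1.0)
        assert st.spearman_rho(x, -np.exp(x / 3)) == pytest.approx(-1.0)

    def test_tied_data_matches_midrank_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 7.0])
        y = np.array([3.0, 3.0, 1.0, 4.0, 4.0, 6.0, 5.0, 5.0])

        def midranks(v):
            out = np.empty_like(v)
            for i, vi in enumerate(v):
                out[i] = np.sum(v < vi) + 0.5 * (np.sum(v == vi) - 1) + 1
            return out

        rx, ry = midranks(x), midranks(y)
        rho_oracle = np.corrcoef(rx, ry)[0, 1]
        assert st.spearman_rho(x, y) == pytest.approx(rho_oracle, abs=1e-12)
        assert st.spearman_rho(x, y) == pytest.approx(sps.spearmanr(x, y).statistic, abs=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(hst.integers(min_value=0, max_value=10_000))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        base = st.spearman_rho(x, y)
        assert st.spearman_rho(np.exp(x), y) == pytest.approx(base, abs=1e-12)
        assert st.spearman_rho(x, 3 * y + 1) == pytest.approx(base, abs=1e-12)

    def test_zero_rank_variance_is_undefined(self):
        with pytest.warns(UserWarning):
            out = st.spearman_rho(np.ones(5), np.arange(5.0))
        assert np.isnan(out)


class TestDistance:
    def test_tip_at_target_is_zero(self):
        assert st.distance_to_target((1.6, 0.8, 7.6)) == 0.0

    def test_unit_offset_along_one_axis(self):
        assert st.distance_to_target((1.6, 0.8, 8.6)) == pytest.approx(1.0)

    def test_matches_coordinate_arithmetic_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            tip = rng.normal((1.6, 0.8, 7.6), 0.5)
            tip[1] = abs(tip[1])  # stay in the target hemisphere
            expect = np.sqrt(np.sum((tip - np.array([1.6, 0.8, 7.6])) ** 2))
            assert st.distance_to_target(tuple(tip)) == pytest.approx(expect, rel=1e-12)

    def test_opposite_hemisphere_reflected_with_warning(self):
        with pytest.warns(UserWarning, match="hemispheres"):
            d = st.distance_to_target((1.6, -0.8, 7.6))
        assert d == 0.0
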