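"""Statistics layer, checked against independent oracles:

- rmcorr against a brute-force design-matrix ANCOVA (least squares on
  explicit subject dummies) and against pingouin's implementation;
- within-subject ANOVA F ratios against statsmodels' AnovaRM and the
  paired-t identity F = t^2;
- Holm-Sidak against direct enumeration;
- power against the printed paired-design sample sizes.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sst

from steadytorque.stats import (
    holm_sidak,
    min_sample_size,
    paired_power,
    pairwise_comparisons,
    rm_anova,
    rmcorr,
)


def balanced_long(n_subjects, n_obs, rng, effect=1.0, noise=1.0):
    rows = []
    for s in range(n_subjects):
        off_x, off_y = rng.normal(0, 5, 2)
        x = rng.normal(0, 1, n_obs) + off_x
        y = effect * x + off_y + rng.normal(0, noise, n_obs)
        for xi, yi in zip(x, y):
            rows.append({"subject": f"S{s}", "x": xi, "y": yi})
    return pd.DataFrame(rows)


def ancova_oracle(df, x="x", y="y", subject="subject"):
    """Brute-force ANCOVA: explicit dummy design matrices, lstsq."""
    subs = sorted(df[subject].unique())
    d = np.zeros((len(df), len(subs)))
    for i, s in enumerate(df[subject]):
        d[i, subs.index(s)] = 1.0
    yv = df[y].to_numpy(float)
    xv = df[x].to_numpy(float)[:, None]
    full = np.hstack([d, xv])
    sse_red = np.sum((yv - d @ np.linalg.lstsq(d, yv, rcond=None)[0]) ** 2)
    beta = np.linalg.lstsq(full, yv, rcond=None)[0]
    sse_full = np.sum((yv - full @ beta) ** 2)
    ss_x = sse_red - sse_full
    r = np.sign(beta[-1]) * np.sqrt(ss_x / (ss_x + sse_full))
    dof = len(df) - len(subs) - 1
    f_stat = ss_x / (sse_full / dof)
    return r, dof, float(sst.f.sf(f_stat, 1, dof))


class TestRmcorr:
    def test_perfect_within_subject_line(self, rng):
        rows = []
        for s in range(5):
            x = rng.normal(0, 1, 6)
            for xi in x:
                rows.append({"subject": s, "x": xi, "y": 2 * xi + 10 * s})
        res = rmcorr(pd.DataFrame(rows), "x", "y", "subject")
        assert res.r_rm == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "n_sub,n_obs,expected_df", [(13, 8, 90), (14, 6, 69), (11, 4, 32), (12, 3, 23)]
    )
    def test_printed_degrees_of_freedom(self, rng, n_sub, n_obs, expected_df):
        df = balanced_long(n_sub, n_obs, rng)
        assert rmcorr(df, "x", "y", "subject").df == expected_df

    def test_matches_bruteforce_ancova(self, rng):
        df = balanced_long(3, 4, rng, effect=0.7, noise=2.0)
        res = rmcorr(df, "x", "y", "subject")
        r_o, df_o, p_o = ancova_oracle(df)
        assert res.r_rm == pytest.approx(r_o, abs=1e-10)
        assert res.df == df_o
        assert res.p == pytest.approx(p_o, rel=1e-9)

    def test_matches_bruteforce_negative_slope(self, rng):
        df = balanced_long(6, 5, rng, effect=-1.2, noise=1.0)
        res = rmcorr(df, "x", "y", "subject")
        r_o, _, _ = ancova_oracle(df)
        assert res.r_rm == pytest.approx(r_o, abs=1e-10)
        assert res.r_rm < 0

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        df = balanced_long(8, 6, rng, effect=0.5, noise=1.5)
        res = rmcorr(df, "x", "y", "subject")
        pg = pingouin.rm_corr(data=df, x="x", y="y", subject="subject")
        assert res.r_rm == pytest.approx(float(pg["r"].iloc[0]), abs=1e-8)
        assert res.df == int(pg["dof"].iloc[0])
        assert res.p == pytest.approx(float(pg["pval"].iloc[0]), rel=1e-6)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=15, deadline=None)
    def test_invariant_to_per_subject_offsets(self, seed):
        rng = np.random.default_rng(seed)
        df = balanced_long(4, 5, rng, effect=0.8)
        res1 = rmcorr(df, "x", "y", "subject")
        shifted = df.copy()
        offsets = {s: rng.normal(0, 50, 2) for s in shifted["subject"].unique()}
        shifted["x"] += shifted["subject"].map(lambda s: offsets[s][0])
        shifted["y"] += shifted["subject"].map(lambda s: offsets[s][1])
        res2 = rmcorr(shifted, "x", "y", "subject")
        assert res2.r_rm == pytest.approx(res1.r_rm, abs=1e-9)

    def test_ci_contains_r(self, rng):
        res = rmcorr(balanced_long(10, 6, rng, effect=0.6), "x", "y", "subject")
        assert res.ci95[0] <= res.r_rm <= res.ci95[1]

    def test_subject_with_single_observation_errors(self):
        df = pd.DataFrame({
            "subject": ["a", "a", "b"], "x": [1.0, 2.0, 3.0], "y": [1.0, 2.0, 3.0]
        })
        with pytest.raises(ValueError, match="b"):
            rmcorr(df, "x", "y", "subject")


def anova_long(y, subjects=None):
    """y: n x k matrix -> one-way long frame."""
    n, k = y.shape
    rows = []
    for i in range(n):
        for j in range(k):
            rows.append({
                "subject": f"S{i}" if subjects is None else subjects[i],
                "cond": f"c{j}", "y": y[i, j],
            })
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_identical_cells_f_zero(self):
        df = anova_long(np.full((6, 3), 7.0))
        res = rm_anova(df, "y", ["cond"], "subject")[0]
        assert res.F == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_two_levels_no_correction_and_f_equals_t_squared(self, rng):
        y = rng.normal(40, 3, size=(10, 2))
        y[:, 1] += 1.5
        res = rm_anova(anova_long(y), "y", ["cond"], "subject")[0]
        assert res.epsilon_gg == pytest.approx(1.0)
        assert not res.corrected
        t_stat, p_t = sst.ttest_rel(y[:, 0], y[:, 1])
        assert res.F == pytest.approx(t_stat**2, rel=1e-10)
        assert res.p == pytest.approx(p_t, rel=1e-10)

    def test_one_way_matches_statsmodels(self, rng):
        statsmodels = pytest.importorskip("statsmodels.stats.anova")
        y = rng.normal(0, 1, size=(8, 4)) + np.array([0.0, 0.5, 1.0, 0.2])
        df = anova_long(y)
        res = rm_anova(df, "y", ["cond"], "subject")[0]
        sm = statsmodels.AnovaRM(df, "y", "subject", within=["cond"]).fit()
        assert res.F == pytest.approx(float(sm.anova_table["F Value"].iloc[0]), rel=1e-8)
        assert res.p_uncorrected == pytest.approx(
            float(sm.anova_table["Pr > F"].iloc[0]), rel=1e-6
        )

    def test_two_way_matches_statsmodels(self, rng):
        statsmodels = pytest.importorskip("statsmodels.stats.anova")
        n, a, b = 9, 3, 2
        rows = []
        for s in range(n):
            base = rng.normal(0, 1)
            for i in range(a):
                for j in range(b):
                    rows.append({
                        "subject": f"S{s}", "A": f"a{i}", "B": f"b{j}",
                        "y": base + 0.6 * i - 0.4 * j + 0.2 * i * j + rng.normal(0, 1),
                    })
        df = pd.DataFrame(rows)
        results = {r.effect: r for r in rm_anova(df, "y", ["A", "B"], "subject")}
        sm = statsmodels.AnovaRM(df, "y", "subject", within=["A", "B"]).fit().anova_table
        assert results["A"].F == pytest.approx(float(sm.loc["A", "F Value"]), rel=1e-8)
        assert results["B"].F == pytest.approx(float(sm.loc["B", "F Value"]), rel=1e-8)
        assert results["A*B"].F == pytest.approx(float(sm.loc["A:B", "F Value"]), rel=1e-8)

    def test_gg_epsilon_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        y = rng.normal(0, 1, size=(12, 4))
        y[:, 0] *= 3.0  # break sphericity
        df = anova_long(y)
        res = rm_anova(df, "y", ["cond"], "subject")[0]
        eps = pingouin.epsilon(df, dv="y", within="cond", subject="subject", correction="gg")
        assert res.epsilon_gg == pytest.approx(float(eps), abs=1e-8)
        spher = pingouin.sphericity(df, dv="y", within="cond", subject="subject")
        assert res.mauchly_p == pytest.approx(float(spher.pval), rel=1e-6)

    def test_incomplete_subject_dropped_with_warning(self, rng, caplog):
        y = rng.normal(0, 1, size=(6, 3))
        df = anova_long(y)
        df = df[~((df["subject"] == "S0") & (df["cond"] == "c2"))]
        with caplog.at_level("WARNING"):
            res = rm_anova(df, "y", ["cond"], "subject")[0]
        assert res.n_subjects == 5
        assert any("incomplete" in r.message for r in caplog.records)

    def test_too_few_subjects_errors(self):
        df = anova_long(np.zeros((2, 3)))
        with pytest.raises(ValueError, match="3 subjects"):
            rm_anova(df, "y", ["cond"], "subject")

    def test_single_level_factor_errors(self):
        df = anova_long(np.zeros((5, 1)))
        with pytest.raises(ValueError):
            rm_anova(df, "y", ["cond"], "subject")

    def test_injected_effect_detected(self, rng):
        y = rng.normal(40, 1, size=(12, 3))
        y[:, 2] += 2.0
        res = rm_anova(anova_long(y), "y", ["cond"], "subject")[0]
        assert res.p < 0.05


class TestHolmSidak:
    def test_single_p_unchanged(self):
        adj, sig = holm_sidak([0.03])
        assert adj[0] == pytest.approx(0.03)
        assert sig[0]

    def test_enumeration_oracle(self):
        # m = 3, sorted p = (.01, .03, .04):
        # 1-(1-.01)^3, max(prev, 1-(1-.03)^2), max(prev, 1-(1-.04)^1)
        adj, _ = holm_sidak([0.04, 0.01, 0.03])
        exp1 = 1 - 0.99**3
        exp2 = max(exp1, 1 - 0.97**2)
        exp3 = max(exp2, 1 - 0.96)
        assert adj[1] == pytest.approx(exp1, abs=1e-12)
        assert adj[2] == pytest.approx(exp2, abs=1e-12)
        assert adj[0] == pytest.approx(exp3, abs=1e-12)

    def test_all_ones(self):
        adj, sig = holm_sidak([1.0, 1.0, 1.0])
        assert np.all(adj == 1.0) and not np.any(sig)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            holm_sidak([])

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            holm_sidak([0.5, 1.2])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_adjusted_at_least_raw_and_rank_monotone(self, ps):
        adj, _ = holm_sidak(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestPairwise:
    def test_pooled_vs_individual_variance(self, rng):
        y = rng.normal(40, 2, size=(10, 3))
        y[:, 0] += 3.0
        df = anova_long(y)
        pooled = pairwise_comparisons(df, "y", "cond", "subject", pooled=True)
        indiv = pairwise_comparisons(df, "y", "cond", "subject", pooled=False)
        assert {c.variance for c in pooled} == {"pooled"}
        assert {c.variance for c in indiv} == {"individual"}
        assert len(pooled) == 3
        # individual-variance comparison equals the paired t test
        first = indiv[0]
        t_stat, p_raw = sst.ttest_rel(y[:, 0], y[:, 1])
        assert first.t == pytest.approx(float(t_stat), rel=1e-10)
        assert first.p_raw == pytest.approx(float(p_raw), rel=1e-10)


class TestPower:
    def test_null_effect_power_is_alpha(self):
        assert paired_power(0.0, 20, alpha=0.05) == pytest.approx(0.05, abs=1e-9)

    def test_printed_sample_sizes(self):
        assert paired_power(1.0, 10) >= 0.80
        assert paired_power(1.0, 13) >= 0.90
        assert min_sample_size(1.0, 0.80) == 10
        assert min_sample_size(1.0, 0.90) == 13

    def test_min_n_matches_bruteforce_scan(self):
        target = next(n for n in range(2, 51) if paired_power(2.0, n) >= 0.80)
        assert min_sample_size(2.0, 0.80) == target == 5

    def test_monotone_in_n_and_dz(self):
        powers = [paired_power(1.0, n) for n in range(3, 30)]
        assert np.all(np.diff(powers) > 0)
        assert paired_power(1.5, 10) > paired_power(1.0, 10) > paired_power(0.5, 10)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            paired_power(1.0, 1)
        with pytest.raises(ValueError):
            paired_power(1.0, 10, alpha=1.5)
        with pytest.raises(ValueError):
            min_sample_size(0.0, 0.8)
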