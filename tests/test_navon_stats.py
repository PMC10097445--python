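"""Tests of the Navon-task statistics: tagging, ANOVA, posthoc, correlation,
mediation.  Independent oracles: pingouin for the GG-corrected ANOVA,
statsmodels for OLS path coefficients and Holm adjustment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chestmotion.exp2_synth import Exp2Config, generate_exp2_dataset, generate_trials
from chestmotion.navon_stats import (
    condition_summaries,
    correlation_matrix,
    mediation_bootstrap,
    pairwise_comparisons,
    rm_anova_gg,
    tag_shift_trials,
)


class TestTagShiftTrials:
    def test_definition_applied(self):
        assert tag_shift_trials(["G", "L", "L", "G"]) == ["undefined", "shift", "nonshift", "shift"]

    def test_all_same_sequence(self):
        tags = tag_shift_trials(["G"] * 40)
        assert tags.count("nonshift") == 39
        assert tags.count("shift") == 0

    def test_alternating_sequence(self):
        seq = ["G", "L"] * 20
        tags = tag_shift_trials(seq)
        assert tags.count("shift") == 39
        assert tags.count("nonshift") == 0

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(1, 60))
            seq = rng.choice(["G", "L"], size=n).tolist()
            tags = tag_shift_trials(seq)
            assert len(tags) == n
            assert tags.count("undefined") == 1
            assert tags.count("shift") + tags.count("nonshift") == n - 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tag_shift_trials([])


class TestConditionSummaries:
    def _trials(self, rows):
        return pd.DataFrame(rows, columns=["participant", "phase", "trial_kind", "rt", "correct", "trial_index"])

    def test_shift_rt_over_accurate_trials_only(self):
        rows = [("p1", "mixed", k, rt, ok, i) for i, (k, rt, ok) in enumerate([
            ("G", 500.0, True),     # undefined
            ("L", 1000.0, True),    # shift, accurate
            ("G", 9000.0, False),   # shift, inaccurate -> excluded from RT
            ("L", 2000.0, True),    # shift, accurate
            ("L", 700.0, True),     # nonshift
        ])]
        summ = condition_summaries(self._trials(rows))
        assert summ.loc["p1", "shift_rt"] == pytest.approx(1500.0)
        assert summ.loc["p1", "accuracy"] == pytest.approx(2 / 3)
        assert summ.loc["p1", "nonshift_rt"] == pytest.approx(700.0)

    def test_all_correct_gives_accuracy_one(self):
        trials = generate_trials(Exp2Config(n_subjects=4, seed=0,
                                            condition_accuracy={c: 1.0 for c in ("global", "local", "nonshift", "shift")}))
        summ = condition_summaries(trials)
        assert np.allclose(summ["accuracy"], 1.0)

    def test_recovers_planted_condition_means(self):
        """Sample means land within 3 SEM of the generator's condition targets."""
        n_subj = 100
        cfg = Exp2Config(n_subjects=n_subj, seed=12)
        summ = condition_summaries(generate_trials(cfg))
        for cond, col, n_trials in [("global", "global_rt", 20), ("local", "local_rt", 20),
                                    ("nonshift", "nonshift_rt", 19), ("shift", "shift_rt", 20)]:
            mean, sd = cfg.condition_rt[cond]
            # SEM of the grand mean over the cohort's accurate trials
            sem = sd / np.sqrt(n_subj * n_trials * 0.95)
            assert abs(summ[col].mean() - mean) <= 3 * sem, cond

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            condition_summaries(pd.DataFrame({"participant": [], "rt": []}))


class TestRmAnovaGG:
    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        data = rng.normal(1000, 300, (28, 1)) + rng.normal(0, 200, (28, 4)) + np.array([0.0, 150, 400, 500])
        res = rm_anova_gg(data)
        long = pd.DataFrame({
            "subj": np.repeat(np.arange(28), 4),
            "cond": np.tile(np.arange(4), 28),
            "y": data.ravel(),
        })
        pa = pg.rm_anova(data=long, dv="y", within="cond", subject="subj",
                         correction=True, detailed=True).iloc[0]
        assert res.F == pytest.approx(pa["F"], rel=1e-9)
        assert res.epsilon == pytest.approx(pa["eps"], rel=1e-9)
        assert res.p == pytest.approx(pa["p_GG_corr"], rel=1e-6)

    def test_two_conditions_reduce_to_paired_t(self):
        rng = np.random.default_rng(6)
        d = rng.normal(0, 1, (15, 2)) + [0.0, 0.4]
        res = rm_anova_gg(d)
        t = stats.ttest_rel(d[:, 0], d[:, 1])
        assert res.epsilon == 1.0
        assert res.F == pytest.approx(t.statistic**2, rel=1e-10)
        assert res.p == pytest.approx(t.pvalue, rel=1e-10)

    def test_df_identities(self):
        rng = np.random.default_rng(7)
        res = rm_anova_gg(rng.normal(size=(28, 4)))
        assert res.df1 == pytest.approx(res.epsilon * 3)
        assert res.df2 == pytest.approx(res.epsilon * 3 * 27)
        assert 1 / 3 <= res.epsilon <= 1.0

    def test_null_p_values_uniform(self):
        """Under exchangeable null data the GG-corrected p is ~uniform."""
        rng = np.random.default_rng(8)
        ps = [rm_anova_gg(rng.normal(size=(12, 4))).p for _ in range(300)]
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_spherical_data_epsilon_near_one(self):
        rng = np.random.default_rng(9)
        eps = [rm_anova_gg(rng.normal(size=(28, 4))).epsilon for _ in range(500)]
        assert np.median(eps) >= 0.9

    def test_missing_cells_rejected(self):
        d = np.ones((5, 3))
        d[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            rm_anova_gg(d)


class TestPairwise:
    def test_t_equals_diff_over_se(self):
        rng = np.random.default_rng(10)
        data = rng.normal(1000, 200, (20, 4)) + [0, 100, 300, 400]
        for r in pairwise_comparisons(data):
            assert r.t == pytest.approx(r.diff / r.se, rel=1e-12)
            assert r.p_bonf == pytest.approx(min(1.0, 6 * r.p_raw), rel=1e-12)

    def test_identical_columns_give_zero_t(self):
        rng = np.random.default_rng(11)
        base = rng.normal(0, 1, (10, 1))
        noise = rng.normal(0, 1, (10, 2))
        data = np.column_stack([base + noise[:, :1], base + noise[:, :1],
                                base + noise[:, 1:], base + 2 * noise[:, 1:]])
        res = {r.pair: r for r in pairwise_comparisons(data, ("a", "b", "c", "d"))}
        r = res[("a", "b")]
        assert r.diff == 0.0
        assert r.t == 0.0
        assert r.p_bonf == 1.0

    def test_holm_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(12)
        data = rng.normal(0, 1, (15, 4)) + [0, 0.2, 0.5, 0.9]
        res = pairwise_comparisons(data)
        p_raw = [r.p_raw for r in res]
        _, holm, _, _ = multipletests(p_raw, method="holm")
        assert np.allclose([r.p_holm for r in res], holm, rtol=1e-10)


class TestCorrelation:
    def test_self_correlation_is_one(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [2.0, 1, 4, 3]})
        r, p, n = correlation_matrix(df)
        assert r.loc["x", "x"] == 1.0

    def test_perfect_negative(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"x": x, "y": -x})
        r, p, _ = correlation_matrix(df)
        assert r.loc["x", "y"] == pytest.approx(-1.0)
        assert p.loc["x", "y"] < 1e-10

    def test_pairwise_deletion_counts(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4, 5], "y": [1.0, np.nan, 3, np.nan, 5]})
        _, _, n = correlation_matrix(df)
        assert n.loc["x", "y"] == 3
        assert n.loc["x", "x"] == 5

    def test_zero_variance_reported_missing(self):
        df = pd.DataFrame({"x": [1.0, 1, 1, 1], "y": [1.0, 2, 3, 4]})
        r, _, _ = correlation_matrix(df)
        assert np.isnan(r.loc["x", "y"])

    def test_simulation_recovers_rho(self):
        rng = np.random.default_rng(13)
        rho = 0.5
        rs = []
        for _ in range(1000):
            z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=28)
            rs.append(np.corrcoef(z.T)[0, 1])
        assert abs(np.mean(rs) - rho) <= 0.03


@pytest.fixture(scope="module")
def default_result():
    tab = generate_exp2_dataset(Exp2Config(n_subjects=28, seed=21))
    return mediation_bootstrap(tab, n_boot=200, seed=3)


class TestMediation:
    def test_total_equals_direct_plus_indirect(self, default_result):
        for effs in default_result.effects.values():
            assert effs["total"].estimate == pytest.approx(
                effs["direct"].estimate + effs["indirect"].estimate, abs=1e-10)

    def test_same_seed_identical_cis(self):
        tab = generate_exp2_dataset(Exp2Config(n_subjects=28, seed=22))
        r1 = mediation_bootstrap(tab, n_boot=100, seed=5)
        r2 = mediation_bootstrap(tab, n_boot=100, seed=5)
        for key in r1.effects:
            for eff in ("direct", "indirect", "total"):
                assert r1.effects[key][eff].ci_low == r2.effects[key][eff].ci_low
                assert r1.effects[key][eff].ci_high == r2.effects[key][eff].ci_high

    def test_point_estimates_match_statsmodels(self):
        import statsmodels.api as sm

        tab = generate_exp2_dataset(Exp2Config(n_subjects=60, seed=23))
        res = mediation_bootstrap(tab, n_boot=10, seed=0)
        base = tab.dropna(subset=["swinging", "rotating", "sitting", "reaction_time", "accuracy"])
        Xm = sm.add_constant(base[["swinging", "rotating", "sitting"]])
        fit_m = sm.OLS(base["reaction_time"], Xm).fit()
        Xy = sm.add_constant(base[["reaction_time", "swinging", "rotating", "sitting"]])
        fit_y = sm.OLS(base["accuracy"], Xy).fit()
        key = ("swinging", "accuracy")
        a = fit_m.params["swinging"]
        b = fit_y.params["reaction_time"]
        assert res.effects[key]["indirect"].estimate == pytest.approx(a * b, rel=1e-8)
        assert res.effects[key]["direct"].estimate == pytest.approx(fit_y.params["swinging"], rel=1e-8)
        assert res.effects[key]["direct"].se == pytest.approx(fit_y.bse["swinging"], rel=1e-8)
        assert res.r_squared["accuracy"] == pytest.approx(fit_y.rsquared, rel=1e-8)

    def test_missing_stress_rows_used_for_accuracy_only(self, default_result):
        assert default_result.n_used["stress"] < default_result.n_used["accuracy"]

    def test_too_few_rows_rejected(self):
        tab = generate_exp2_dataset(Exp2Config(n_subjects=8, seed=24))
        with pytest.raises(ValueError, match="10 complete rows"):
            mediation_bootstrap(tab, n_boot=10, seed=0)

    def test_standardized_estimates_scale_free(self):
        """Standardized path estimates are invariant to variable rescaling."""
        tab = generate_exp2_dataset(Exp2Config(n_subjects=40, seed=25))
        r1 = mediation_bootstrap(tab, n_boot=10, seed=0)
        tab2 = tab.copy()
        tab2["reaction_time"] = tab2["reaction_time"] / 1000.0  # seconds
        r2 = mediation_bootstrap(tab2, n_boot=10, seed=0)
        k = ("swinging", "accuracy")
        for eff in ("direct", "indirect", "total"):
            assert r1.effects[k][eff].std_estimate == pytest.approx(
                r2.effects[k][eff].std_estimate, rel=1e-8)
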