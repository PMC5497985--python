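"""Group statistics against brute-force formula oracles and pingouin."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import teplab as T
from teplab.stats import mixed_anova_ss


class TestExcludeOutliers:
    def test_constant_vector_keeps_all(self):
        assert T.exclude_outliers([5.0] * 8).all()

    def test_single_value_kept(self):
        assert T.exclude_outliers([3.0]).all()

    def test_spike_exclusion_matches_arithmetic(self):
        x = np.array([0.0] * 9 + [50.0])
        mean, sd = x.mean(), x.std(ddof=1)
        keep = T.exclude_outliers(x, threshold_sd=2.0)
        for i, v in enumerate(x):
            assert keep[i] == (abs(v - mean) <= 2.0 * sd)
        assert not keep[-1]

    def test_nan_always_excluded(self):
        keep = T.exclude_outliers([1.0, 2.0, np.nan, 3.0])
        assert not keep[2]


class TestTwoSampleT:
    def test_identical_samples(self):
        res = T.two_sample_t([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.statistic == 0.0
        assert res.effect_size == 0.0

    def test_cohens_d_definition(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1.8, 1.0, 4000)
        b = rng.normal(1.0, 1.0, 4000)
        res = T.two_sample_t(a, b)
        assert res.effect_size == pytest.approx(0.8, abs=0.08)

    def test_matches_textbook_formula(self):
        a = np.array([3.1, 2.7, 4.4, 3.8, 2.9])
        b = np.array([2.2, 2.8, 1.9, 3.0, 2.4])
        res = T.two_sample_t(a, b)
        # brute-force pooled t
        na, nb = len(a), len(b)
        sp2 = (sum((x - a.mean()) ** 2 for x in a) + sum((x - b.mean()) ** 2 for x in b)) / (
            na + nb - 2
        )
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.df == na + nb - 2
        assert res.p_raw == pytest.approx(2 * sps.t.sf(abs(t), na + nb - 2), abs=1e-10)
        # cross-check against scipy's pooled t-test
        t_sp, p_sp = sps.ttest_ind(a, b, equal_var=True)
        assert res.statistic == pytest.approx(t_sp, abs=1e-10)
        assert res.p_raw == pytest.approx(p_sp, abs=1e-10)

    def test_zero_variance_unequal_means_errors(self):
        with pytest.raises(T.DegenerateSignalError):
            T.two_sample_t([1.0, 1.0], [2.0, 2.0])

    def test_t_squared_equals_oneway_f(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 9)
        t = T.two_sample_t(a, b).statistic
        f = sps.f_oneway(a, b).statistic
        assert t**2 == pytest.approx(f, abs=1e-10)

    def test_unit_rescaling_invariance(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(3, 1, 10), rng.normal(2, 1, 14)
        r1, r2 = T.two_sample_t(a, b), T.two_sample_t(a * 100, b * 100)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)
        assert r1.effect_size == pytest.approx(r2.effect_size, rel=1e-12)


def _mixed_table(values_by_subject):
    """values_by_subject: dict sid -> (group, value_t1, value_t2)."""
    rows = []
    for sid, (g, v1, v2) in values_by_subject.items():
        rows.append(dict(subject_id=sid, group=g, time="t1", value=v1))
        rows.append(dict(subject_id=sid, group=g, time="t2", value=v2))
    return pd.DataFrame(rows)


class TestMixedAnova:
    def _toy(self):
        return _mixed_table({
            "s1": ("A", 10.0, 14.0), "s2": ("A", 12.0, 13.0),
            "s3": ("A", 9.0, 16.0), "s4": ("A", 11.0, 15.0),
            "s5": ("B", 10.0, 11.0), "s6": ("B", 12.0, 12.0),
            "s7": ("B", 11.0, 10.0), "s8": ("B", 13.0, 12.0),
        })

    def test_constant_values_give_zero_effects(self):
        table = _mixed_table({f"s{i}": ("A" if i < 4 else "B", 5.0, 5.0) for i in range(8)})
        for res in T.mixed_anova_2x2(table):
            assert res.statistic == 0.0
            assert res.effect_size == 0.0

    def test_parallel_change_kills_interaction(self):
        table = _mixed_table({
            "s1": ("A", 10.0, 13.0), "s2": ("A", 12.0, 15.0),
            "s3": ("B", 20.0, 23.0), "s4": ("B", 21.0, 24.0),
        })
        ss = mixed_anova_ss(table)
        assert ss["ss_interaction"] == pytest.approx(0.0, abs=1e-10)

    def test_ss_match_brute_force_decomposition(self):
        """Every SS term equals an independently coded cell/marginal computation."""
        table = self._toy()
        ss = mixed_anova_ss(table)
        wide = table.pivot(index="subject_id", columns="time", values="value")
        groups = table.groupby("subject_id")["group"].first()
        y = table["value"].to_numpy()
        grand = y.mean()

        ss_total = ((y - grand) ** 2).sum()
        ss_between = 0.0
        for sid in wide.index:
            m = wide.loc[sid].mean()
            ss_between += 2 * (m - grand) ** 2
        ss_group = 0.0
        for g in ("A", "B"):
            sel = table[table["group"] == g]["value"]
            n_g = (groups == g).sum()
            ss_group += 2 * n_g * (sel.mean() - grand) ** 2
        ss_time = 0.0
        for t_lvl in ("t1", "t2"):
            sel = table[table["time"] == t_lvl]["value"]
            ss_time += len(wide) * (sel.mean() - grand) ** 2
        ss_inter = 0.0
        for g in ("A", "B"):
            for t_lvl in ("t1", "t2"):
                cell = table[(table["group"] == g) & (table["time"] == t_lvl)]["value"].mean()
                gm = table[table["group"] == g]["value"].mean()
                tm = table[table["time"] == t_lvl]["value"].mean()
                n_g = (groups == g).sum()
                ss_inter += n_g * (cell - gm - tm + grand) ** 2

        assert ss["ss_total"] == pytest.approx(ss_total, abs=1e-10)
        assert ss["ss_group"] == pytest.approx(ss_group, abs=1e-10)
        assert ss["ss_subj_error"] == pytest.approx(ss_between - ss_group, abs=1e-10)
        assert ss["ss_time"] == pytest.approx(ss_time, abs=1e-10)
        assert ss["ss_interaction"] == pytest.approx(ss_inter, abs=1e-10)

    def test_ss_conservation(self):
        rng = np.random.default_rng(2)
        table = _mixed_table({
            f"s{i}": ("A" if i < 7 else "B", rng.normal(), rng.normal()) for i in range(12)
        })
        ss = mixed_anova_ss(table)
        total = (ss["ss_group"] + ss["ss_subj_error"] + ss["ss_time"]
                 + ss["ss_interaction"] + ss["ss_time_error"])
        assert total == pytest.approx(ss["ss_total"], abs=1e-10)

    @pytest.mark.parametrize("n_a,n_b", [(4, 4), (7, 5)])
    def test_matches_pingouin(self, n_a, n_b):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(n_a * 10 + n_b)
        table = _mixed_table({
            f"s{i}": ("A" if i < n_a else "B",
                      rng.normal(10, 2), rng.normal(11, 2))
            for i in range(n_a + n_b)
        })
        mine = {r.name: r for r in T.mixed_anova_2x2(table)}
        aov = pingouin.mixed_anova(data=table, dv="value", within="time",
                                   subject="subject_id", between="group")
        ref = {row["Source"]: row for _, row in aov.iterrows()}
        for mine_key, pg_key in [("Group", "group"), ("Time", "time"),
                                 ("Group x Time", "Interaction")]:
            assert mine[mine_key].statistic == pytest.approx(ref[pg_key]["F"], rel=1e-8)
            assert mine[mine_key].p_raw == pytest.approx(ref[pg_key]["p_unc"], rel=1e-8)
            if not np.isnan(ref[pg_key].get("np2", np.nan)):
                assert mine[mine_key].effect_size == pytest.approx(ref[pg_key]["np2"], rel=1e-8)

    def test_missing_time_level_rejected(self):
        table = self._toy().iloc[:-1]
        with pytest.raises(T.SpecError):
            T.mixed_anova_2x2(table)


class TestPearsonR:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        res = T.pearson_r(x, 2 * x + 1)
        assert res.statistic == pytest.approx(1.0)

    def test_orthogonal_gives_zero(self):
        rng = np.random.default_rng(1)
        xc = rng.normal(size=50)
        xc -= xc.mean()
        yc = rng.normal(size=50)
        yc -= yc.mean()
        yc -= xc * (xc @ yc) / (xc @ xc)  # orthogonalize against x
        res = T.pearson_r(xc, yc)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_covariance_formula(self):
        x = np.array([1.0, 2.0, 4.0, 4.5, 7.0, 9.0])
        y = np.array([2.2, 2.8, 3.9, 5.5, 6.1, 8.4])
        r_brute = (((x - x.mean()) * (y - y.mean())).sum()
                   / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        res = T.pearson_r(x, y)
        assert res.statistic == pytest.approx(r_brute, abs=1e-12)
        assert res.df == len(x) - 2

    def test_constant_input_rejected(self):
        with pytest.raises(T.DegenerateSignalError):
            T.pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBonferroni:
    @pytest.mark.parametrize("p,m,expected", [(0.03, 7, 0.21), (0.2, 1, 0.2), (0.5, 3, 1.0)])
    def test_values(self, p, m, expected):
        assert T.bonferroni(p, m) == pytest.approx(expected)

    def test_monotone_and_capped(self):
        ps = np.linspace(0, 1, 21)
        for m in (1, 2, 5, 20):
            vals = [T.bonferroni(p, m) for p in ps]
            assert all(a <= b for a, b in zip(vals, vals[1:]))
            assert max(vals) <= 1.0


class TestCompareGroups:
    def _data(self, seed=0, delta=0.0, n_a=16, n_b=35):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(dict(
            subject_id=[f"s{i}" for i in range(n_a + n_b)],
            group=["A"] * n_a + ["B"] * n_b,
            m1=np.r_[rng.normal(delta, 1, n_a), rng.normal(0, 1, n_b)],
            m2=rng.normal(0, 1, n_a + n_b),
        ))

    def test_unknown_measure_lists_known(self):
        with pytest.raises(T.SpecError, match="m1"):
            T.compare_groups(self._data(), ["nope"])

    def test_single_measure_no_correction(self):
        res = T.compare_groups(self._data(), ["m1"])
        assert res.loc[0, "p_corrected"] is None or pd.isna(res.loc[0, "p_corrected"])

    def test_bonferroni_applied_across_measures(self):
        res = T.compare_groups(self._data(), ["m1", "m2"])
        for _, row in res.iterrows():
            assert row["p_corrected"] == pytest.approx(min(1.0, row["p_raw"] * 2))

    def test_mixed_design_emits_three_rows(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(10):
            g = "A" if i < 5 else "B"
            rows.append(dict(subject_id=f"s{i}", group=g, time="t1", m=rng.normal()))
            rows.append(dict(subject_id=f"s{i}", group=g, time="t2", m=rng.normal()))
        res = T.compare_groups(pd.DataFrame(rows), ["m"], design="mixed")
        assert list(res["contrast"]) == ["Group", "Time", "Group x Time"]

    def test_two_sd_exclusion_inflates_type_one_error(self):
        """Per-group 2-SD exclusion before a t-test is anticonservative at
        n = 16/35: the rejection rate under the null roughly doubles. This
        characterizes the exclusion rule rather than asserting calibration."""
        n_rep = 400
        with_excl = without_excl = 0
        for rep in range(n_rep):
            rng = np.random.default_rng(20_000 + rep)
            data = pd.DataFrame(dict(
                group=["A"] * 16 + ["B"] * 35,
                m=np.r_[rng.normal(0, 1, 16), rng.normal(0, 1, 35)],
            ))
            with_excl += T.compare_groups(data, ["m"]).loc[0, "p_raw"] < 0.05
            without_excl += (
                T.compare_groups(data, ["m"], threshold_sd=None).loc[0, "p_raw"] < 0.05
            )
        assert without_excl / n_rep == pytest.approx(0.05, abs=0.025)
        assert 0.06 <= with_excl / n_rep <= 0.16

    def test_empirical_power_matches_analytic(self):
        """Power at d = 0.8, n = 16 vs 35 within ±5 points of the analytic value."""
        from statsmodels.stats.power import TTestIndPower

        analytic = TTestIndPower().power(effect_size=0.8, nobs1=16, ratio=35 / 16,
                                         alpha=0.05, alternative="two-sided")
        hits = 0
        n_rep = 500
        for rep in range(n_rep):
            data = self._data(seed=1000 + rep, delta=0.8)
            res = T.compare_groups(data, ["m1"], threshold_sd=None)
            hits += res.loc[0, "p_raw"] < 0.05
        assert hits / n_rep == pytest.approx(analytic, abs=0.05)
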