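import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phage_edna.bim_stats import (
    DegenerateVarianceError,
    MissingBaselineError,
    anova_tukey,
    assign_moi_bin,
    bartlett_test,
    daily_baseline,
    games_howell,
    log2_fold_change,
    per_moi_analysis,
    percent_change,
    select_and_run,
    welch_anova,
)


def make_plates(records):
    return pd.DataFrame(
        records, columns=["day_id", "lysate_id", "condition", "moi", "cfu"]
    )


class TestBaselineNormalisation:
    def test_baseline_is_daily_mean(self):
        df = make_plates(
            [
                ("d1", "l1", "untreated", 0.3, 90),
                ("d1", "l1", "untreated", 0.3, 110),
                ("d1", "l1", "dnase", 0.3, 60),
            ]
        )
        assert daily_baseline(df).to_dict() == {"d1": 100.0}

    def test_single_observation_is_its_own_baseline(self):
        df = make_plates([("d1", "l1", "untreated", 0.3, 73)])
        assert daily_baseline(df).to_dict() == {"d1": 73.0}

    def test_no_cross_day_pooling(self):
        df = make_plates(
            [
                ("d1", "l1", "untreated", 0.3, 100),
                ("d1", "l1", "dnase", 0.3, 60),
                ("d2", "l2", "untreated", 0.3, 200),
                ("d2", "l2", "dnase", 0.3, 120),
            ]
        )
        base = daily_baseline(df)
        assert base.to_dict() == {"d1": 100.0, "d2": 200.0}
        fc = log2_fold_change(df, base)
        dnase = fc[fc.condition == "dnase"]
        # both days give the same fold change against their own baseline
        assert dnase["log2fc"].to_numpy() == pytest.approx(
            [math.log2(0.6), math.log2(0.6)]
        )

    def test_missing_baseline_day_reported(self):
        df = make_plates(
            [
                ("d1", "l1", "untreated", 0.3, 100),
                ("d2", "l2", "dnase", 0.3, 50),
            ]
        )
        with pytest.raises(MissingBaselineError, match="d2"):
            daily_baseline(df)

    def test_log2_fold_change_values(self):
        df = make_plates(
            [
                ("d1", "l1", "untreated", 0.3, 100),
                ("d1", "l1", "dnase", 0.3, 60),
                ("d1", "l1", "purified", 0.3, 0),
            ]
        )
        fc = log2_fold_change(df, {"d1": 100.0})
        by_cond = fc.set_index("condition")
        assert by_cond.loc["untreated", "log2fc"] == pytest.approx(0.0)
        assert by_cond.loc["dnase", "log2fc"] == pytest.approx(-0.737, abs=1e-3)
        # zero counts get the pseudo-count and a flag, not removal
        assert by_cond.loc["purified", "zero_flag"]
        assert by_cond.loc["purified", "log2fc"] == pytest.approx(math.log2(0.005))

    def test_rescaling_invariance(self):
        """Multiplying a day's counts and baseline by one factor leaves
        every fold change unchanged."""
        df = make_plates(
            [("d1", "l1", "untreated", 0.3, 80), ("d1", "l1", "dnase", 0.3, 48)]
        )
        fc1 = log2_fold_change(df, {"d1": 80.0})
        scaled = df.assign(cfu=df.cfu * 7)
        fc2 = log2_fold_change(scaled, {"d1": 560.0})
        assert fc1["log2fc"].to_numpy() == pytest.approx(fc2["log2fc"].to_numpy())

    def test_nonpositive_baseline_rejected(self):
        df = make_plates([("d1", "l1", "untreated", 0.3, 10)])
        with pytest.raises(ValueError):
            log2_fold_change(df, {"d1": 0.0})


class TestBartlett:
    def test_equal_variances_give_zero_statistic(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        stat, p = bartlett_test([base, base + 10.0, base - 3.0])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_large_variance_ratio_detected(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1.0, 20)
        b = rng.normal(0, 4.0, 20)  # variance ratio 16
        _, p = bartlett_test([a, b])
        assert p < 0.01

    def test_type_i_error_calibrated(self):
        """Under the null (same normal), rejection at alpha=0.05 happens
        about 5% of the time."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_sim = 10_000
        for _ in range(n_sim):
            groups = rng.normal(0.0, 1.0, size=(3, 10))
            stat, p = bartlett_test(list(groups))
            rejections += p < 0.05
        assert 0.04 <= rejections / n_sim <= 0.06

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            bartlett_test([[1.0, 2.0], [3.0]])


class TestWelchAnova:
    def test_two_groups_equal_welch_t_squared(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 2.5, 9)
        f, df1, df2, p = welch_anova([a, b])
        t_res = stats.ttest_ind(a, b, equal_var=False)
        assert f == pytest.approx(t_res.statistic**2)
        assert p == pytest.approx(t_res.pvalue)
        assert df2 == pytest.approx(t_res.df)

    def test_identical_groups_give_zero_f(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        f, *_, p = welch_anova([g, g.copy(), g.copy()])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_zero_variance_group_raises(self):
        with pytest.raises(DegenerateVarianceError):
            welch_anova([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])

    def test_close_to_classical_f_when_homoscedastic(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(m, 1.0, 100) for m in (0.0, 0.3, 0.6)]
        f_welch, *_ = welch_anova(groups)
        f_classic, _ = stats.f_oneway(*groups)
        assert abs(f_welch - f_classic) / f_classic < 0.05


class TestGamesHowell:
    def test_identical_pair_not_significant(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        (res,) = games_howell([g, g.copy()])
        assert res.estimate == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_separated_group_detected(self):
        groups = [[1.0, 2.0, 3.0], [2.0, 3.0, 4.0], [10.0, 11.0, 12.0]]
        res = {(r.group_a, r.group_b): r for r in games_howell(groups)}
        assert res[("group0", "group2")].p < 0.01
        assert res[("group0", "group1")].p > 0.1

    def test_matches_pingouin(self):
        """Cross-check statistics, df and p against an independent
        implementation."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        sizes = {"a": 12, "b": 15, "c": 10}
        groups = {
            k: rng.normal(m, s, n)
            for (k, n), m, s in zip(sizes.items(), (0, 0.5, 1.2), (1, 2, 0.7))
        }
        ours = {
            (r.group_a, r.group_b): r
            for r in games_howell(list(groups.values()), list(groups))
        }
        df = pd.DataFrame(
            {
                "y": np.concatenate(list(groups.values())),
                "grp": np.repeat(list(groups), list(sizes.values())),
            }
        )
        ref = pg.pairwise_gameshowell(df, dv="y", between="grp")
        for _, row in ref.iterrows():
            r = ours[(row["A"], row["B"])]
            assert r.estimate == pytest.approx(row["diff"], rel=1e-9)
            assert r.df == pytest.approx(row["df"], rel=1e-9)
            assert r.p == pytest.approx(row["pval"], rel=1e-6, abs=1e-12)

    def test_tukey_equivalence_on_homoscedastic_balanced_groups(self):
        """With exactly equal variances and equal n, Games-Howell reduces
        to Tukey HSD up to the small residual-df difference."""
        rng = np.random.default_rng(3)
        base = rng.normal(0.0, 1.0, 100)
        groups = [base + shift for shift in (0.0, 0.15, 0.3)]
        gh = games_howell(groups)
        _, _, tukey = anova_tukey(groups)
        for a, b in zip(gh, tukey):
            assert abs(a.p - b.p) / b.p < 0.02


class TestAnovaTukey:
    def test_identical_groups(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        f, p, pairs = anova_tukey([g, g.copy(), g.copy()])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert all(r.p == pytest.approx(1.0) for r in pairs)

    def test_two_groups_equal_pooled_t_squared(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        f, p, _ = anova_tukey([a, b])
        t_res = stats.ttest_ind(a, b, equal_var=True)
        assert f == pytest.approx(t_res.statistic**2)
        assert p == pytest.approx(t_res.pvalue)

    def test_closed_form_f(self):
        groups = [
            np.array([5.0, 6.0, 7.0]),
            np.array([8.0, 9.0, 10.0]),
            np.array([11.0, 12.0, 13.0]),
        ]
        f, _, _ = anova_tukey(groups)
        grand = np.mean(np.concatenate(groups))
        ms_between = sum(3 * (g.mean() - grand) ** 2 for g in groups) / 2
        mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / 6
        assert f == pytest.approx(ms_between / mse)


class TestDecisionProcedure:
    def test_homoscedastic_equal_n_goes_classical(self):
        base = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        groups = {"untreated": base, "dnase": base + 1, "buffer": base - 1}
        report = select_and_run(groups, control="untreated")
        assert report.method == "anova_tukey"

    def test_unequal_n_goes_welch(self):
        rng = np.random.default_rng(5)
        groups = {
            "untreated": rng.normal(0, 1, 12),
            "dnase": rng.normal(0, 1, 8),
        }
        report = select_and_run(groups, control="untreated")
        assert report.method == "welch_games_howell"

    def test_unequal_variance_goes_welch(self):
        rng = np.random.default_rng(6)
        groups = {
            "untreated": rng.normal(0, 0.2, 15),
            "dnase": rng.normal(0, 5.0, 15),
        }
        report = select_and_run(groups, control="untreated")
        assert report.bartlett_p < 0.05
        assert report.method == "welch_games_howell"

    def test_control_only_comparisons_by_default(self):
        rng = np.random.default_rng(7)
        groups = {
            "untreated": rng.normal(0, 1, 10),
            "a": rng.normal(0, 1, 10),
            "b": rng.normal(0, 1, 10),
        }
        report = select_and_run(groups, control="untreated")
        assert len(report.pairwise) == 2
        assert all("untreated" in (r.group_a, r.group_b) for r in report.pairwise)
        full = select_and_run(groups, control="untreated", comparisons="all_pairs")
        assert len(full.pairwise) == 3

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError):
            select_and_run({"a": np.ones(3), "b": np.zeros(3)}, control="untreated")

    def test_zero_variance_falls_back_with_warning(self):
        groups = {
            "untreated": np.array([1.0, 1.0, 1.0]),
            "dnase": np.array([1.0, 2.0, 3.0, 4.0]),
        }
        with pytest.warns(UserWarning):
            report = select_and_run(groups, control="untreated")
        assert report.method == "anova_tukey"
        assert report.warnings

    def test_per_moi_bins_are_independent(self):
        rng = np.random.default_rng(8)
        rows = []
        for moi in (0.2, 0.35):
            for cond, shift in (("untreated", 0.0), ("dnase", -1.0 if moi < 0.3 else 0.0)):
                for i in range(10):
                    rows.append(
                        {
                            "condition": cond,
                            "moi": moi + rng.normal(0, 0.005),
                            "log2fc": shift + rng.normal(0, 0.3),
                        }
                    )
        df = pd.DataFrame(rows)
        reports = per_moi_analysis(df, control="untreated")
        assert set(reports) == {0.2, 0.35}
        assert reports[0.2].pairwise[0].p < 0.01
        assert reports[0.35].pairwise[0].p > 0.1

    def test_moi_binning_nearest(self):
        assert assign_moi_bin(np.array([0.33, 0.37, 0.02]), 0.05) == pytest.approx(
            [0.35, 0.35, 0.0]
        )


class TestPercentChange:
    def test_identical_groups_zero(self):
        g = np.array([10.0, 12.0, 11.0])
        assert percent_change(g, g).value == pytest.approx(0.0)

    def test_delta_method_oracle(self):
        """mean_t 60+/-3 vs mean_c 100+/-4 -> 40% with sd ~ 3.9."""
        rng = np.random.default_rng(9)
        n = 40
        treated = 60.0 + rng.normal(0, 3 * math.sqrt(n), n)
        control = 100.0 + rng.normal(0, 4 * math.sqrt(n), n)
        # Shift to hit the target means/sems exactly.
        treated += 60.0 - treated.mean()
        control += 100.0 - control.mean()
        treated = 60.0 + (treated - 60.0) * (3 * math.sqrt(n) / treated.std(ddof=1))
        control = 100.0 + (control - 100.0) * (4 * math.sqrt(n) / control.std(ddof=1))
        pc = percent_change(treated, control)
        assert pc.value == pytest.approx(40.0, abs=1e-9)
        expected_sd = math.hypot(100.0 / 100.0 * 3.0, 100.0 * 60.0 / 100.0**2 * 4.0)
        assert pc.sd == pytest.approx(expected_sd, rel=1e-6)
        assert expected_sd == pytest.approx(3.84, abs=0.1)

    def test_increase_has_negative_sign(self):
        treated = np.array([170.0, 170.0, 170.0])
        control = np.array([100.0, 100.0, 100.0])
        assert percent_change(treated, control).value == pytest.approx(-70.0)

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            percent_change(np.array([1.0, 2.0]), np.array([-1.0, 1.0]))

    def test_log2_mode_uses_geometric_means(self):
        treated = np.log2(np.array([0.5, 0.6, 0.72]))
        control = np.log2(np.array([1.0, 1.2, 0.83]))
        pc = percent_change(treated, control, mode="log2")
        gm_ratio = 2.0 ** (treated.mean() - control.mean())
        assert pc.value == pytest.approx(100.0 * (1 - gm_ratio))
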