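"""Group statistics: hand-computed values, algebraic identities, a
design-matrix brute-force oracle, and a cross-check against pingouin."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import hemoconn as hc


def glm_mixed_anova_oracle(table):
    """Brute-force mixed 2x2 ANOVA via projection sums of squares.

    Between stratum: one-way ANOVA of subject means on group.
    Within stratum: the per-subject condition difference d carries the
    condition effect (intercept of d, unweighted over groups) and the
    interaction (group effect on d); the error is the pooled within-group
    variance of the respective contrast.
    """
    wide = table.pivot_table(index=["subject", "group"], columns="condition",
                             values="value").reset_index()
    conds = [c for c in wide.columns if c not in ("subject", "group")]
    groups = sorted(wide["group"].unique())
    m = [(wide[wide["group"] == g][conds[0]].to_numpy()
          + wide[wide["group"] == g][conds[1]].to_numpy()) / 2 for g in groups]
    d = [(wide[wide["group"] == g][conds[1]].to_numpy()
          - wide[wide["group"] == g][conds[0]].to_numpy()) for g in groups]
    n1, n2 = len(m[0]), len(m[1])
    dfe = n1 + n2 - 2

    def between_f(a, b):
        sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / dfe
        return (a.mean() - b.mean()) ** 2 / (sp2 * (1 / n1 + 1 / n2))

    f_group = between_f(m[0], m[1])
    est = 0.5 * (d[0].mean() + d[1].mean())
    sp2 = (((d[0] - d[0].mean()) ** 2).sum()
           + ((d[1] - d[1].mean()) ** 2).sum()) / dfe
    f_cond = est ** 2 / (sp2 * (1 / n1 + 1 / n2) / 4)
    f_inter = between_f(d[0], d[1])
    return f_group, f_cond, f_inter


def make_table(values, groups, rng=None):
    rows = []
    for s, (g, (v_rest, v_stand)) in enumerate(zip(groups, values)):
        rows.append({"subject": f"s{s}", "group": g,
                     "condition": "resting", "value": v_rest})
        rows.append({"subject": f"s{s}", "group": g,
                     "condition": "standing", "value": v_stand})
    return pd.DataFrame(rows)


class TestAssumptionChecks:
    def test_levene_zero_for_identical_groups(self, rng):
        x = rng.standard_normal(20)
        res = hc.assumption_checks({"a": x, "b": x.copy()})
        assert res["levene"].statistic == pytest.approx(0.0, abs=1e-12)

    def test_levene_equals_anova_on_absolute_deviations(self, rng):
        a, b = rng.standard_normal(15), 2.5 * rng.standard_normal(12)
        res = hc.assumption_checks({"a": a, "b": b})
        f = hc.one_way_anova(np.abs(a - a.mean()), np.abs(b - b.mean()))
        assert res["levene"].statistic == pytest.approx(f.statistic, abs=1e-10)
        assert res["levene"].p == pytest.approx(f.p, abs=1e-10)

    def test_ks_statistic_bounded(self, rng):
        res = hc.assumption_checks({"a": rng.standard_normal(30),
                                    "b": rng.standard_normal(30)})
        assert 0.0 <= res["ks"].statistic <= 1.0

    def test_constant_group_flagged(self):
        res = hc.assumption_checks({"a": np.ones(5),
                                    "b": np.array([1.0, 2.0, 3.0])})
        assert np.isnan(res["levene"].statistic)
        assert res["levene"].extra["flag"] == "constant group"


class TestOneWayAnova:
    def test_identical_groups_zero(self):
        res = hc.one_way_anova(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert res.statistic == 0.0

    def test_degenerate_separation_infinite(self):
        res = hc.one_way_anova(np.array([0.0, 0.0]), np.array([1.0, 1.0]))
        assert np.isinf(res.statistic) and res.p == 0.0

    def test_hand_computed_example(self):
        # means 2.5 vs 4.5, SS_between = 8, SS_within = 10 on 6 df -> F = 4.8
        res = hc.one_way_anova(np.array([1.0, 2, 3, 4]),
                               np.array([3.0, 4, 5, 6]))
        assert res.statistic == pytest.approx(8 / (10 / 6), abs=1e-12)
        assert res.df == (1, 6)

    def test_matches_scipy(self, rng):
        a, b, c = (rng.standard_normal(n) for n in (8, 11, 9))
        ours = hc.one_way_anova(a, b, c)
        ref = sps.f_oneway(a, b, c)
        assert ours.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert ours.p == pytest.approx(ref.pvalue, abs=1e-10)


class TestMixedAnova:
    def test_pure_condition_effect(self):
        base = np.array([1.0, 2.0, 3.0, 1.5, 2.5, 3.5])
        values = [(b, b + 2.0) for b in base]
        table = make_table(values, ["g1"] * 3 + ["g2"] * 3)
        res = hc.mixed_anova_2x2(table)
        assert np.isinf(res["condition"].statistic)
        assert res["condition"].p == 0.0
        assert res["interaction"].statistic == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_glm_oracle_balanced(self, rng):
        values = [tuple(v) for v in rng.standard_normal((6, 2))]
        table = make_table(values, ["g1"] * 3 + ["g2"] * 3)
        res = hc.mixed_anova_2x2(table)
        f_g, f_c, f_i = glm_mixed_anova_oracle(table)
        assert res["group"].statistic == pytest.approx(f_g, abs=1e-8)
        assert res["condition"].statistic == pytest.approx(f_c, abs=1e-8)
        assert res["interaction"].statistic == pytest.approx(f_i, abs=1e-8)

    def test_agrees_with_glm_oracle_unbalanced(self, rng):
        values = [tuple(v) for v in rng.standard_normal((9, 2))]
        table = make_table(values, ["g1"] * 4 + ["g2"] * 5)
        res = hc.mixed_anova_2x2(table)
        f_g, f_c, f_i = glm_mixed_anova_oracle(table)
        assert res["group"].statistic == pytest.approx(f_g, abs=1e-8)
        assert res["condition"].statistic == pytest.approx(f_c, abs=1e-8)
        assert res["interaction"].statistic == pytest.approx(f_i, abs=1e-8)

    def test_group_and_interaction_match_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        values = [tuple(v) for v in rng.standard_normal((10, 2))]
        table = make_table(values, ["g1"] * 5 + ["g2"] * 5)
        ours = hc.mixed_anova_2x2(table)
        ref = pg.mixed_anova(data=table, dv="value", within="condition",
                             subject="subject", between="group")
        ref = ref.set_index("Source")
        assert ours["group"].statistic == pytest.approx(
            ref.loc["group", "F"], rel=1e-6)
        assert ours["condition"].statistic == pytest.approx(
            ref.loc["condition", "F"], rel=1e-6)
        assert ours["interaction"].statistic == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-6)

    def test_missing_condition_rejected(self):
        table = make_table([(1.0, 2.0), (2.0, 3.0), (1.0, 1.0)],
                           ["g1", "g1", "g2"])
        table = table.drop(table.index[-1])
        with pytest.raises(ValueError):
            hc.mixed_anova_2x2(table)


class TestRepeatedMeasures:
    def test_identical_pairs_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        res = hc.repeated_measures_comparison(x, x.copy())
        assert res.statistic == 0.0 and res.p == 1.0

    def test_equals_squared_paired_t(self, rng):
        a = rng.standard_normal(12)
        b = a + 0.3 + 0.5 * rng.standard_normal(12)
        res = hc.repeated_measures_comparison(a, b)
        t = sps.ttest_rel(b, a)
        assert res.statistic == pytest.approx(t.statistic ** 2, abs=1e-10)
        assert res.p == pytest.approx(t.pvalue, abs=1e-10)

    def test_constant_shift_infinite(self):
        a = np.array([1.0, 2.0, 3.0])
        res = hc.repeated_measures_comparison(a, a + 1.0)
        assert np.isinf(res.statistic) and res.p == 0.0


class TestIndependentT:
    def test_identical_groups(self):
        x = np.array([1.0, 2.0, 3.0])
        res = hc.independent_t_test(x, x.copy())
        assert res.statistic == 0.0 and res.p == 1.0

    def test_hand_computed_example(self):
        res = hc.independent_t_test(np.array([1.0, 2, 3]),
                                    np.array([4.0, 5, 6]))
        assert res.statistic == pytest.approx(-3.0 / np.sqrt(2 / 3), abs=1e-3)
        assert abs(res.statistic) == pytest.approx(3.674, abs=1e-3)
        assert res.df == (4,)

    def test_t_squared_equals_anova_f(self, rng):
        a, b = rng.standard_normal(9), rng.standard_normal(7) + 0.5
        t = hc.independent_t_test(a, b)
        f = hc.one_way_anova(a, b)
        assert t.statistic ** 2 == pytest.approx(f.statistic, abs=1e-10)
        assert t.p == pytest.approx(f.p, abs=1e-10)


class TestPearson:
    def test_perfect_linear(self):
        x = np.array([1.0, 2, 3, 4])
        assert hc.pearson_correlation(x, 2 * x + 1).statistic == pytest.approx(1.0)
        assert hc.pearson_correlation(x, -x).statistic == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        res = hc.pearson_correlation(np.array([1.0, 2, 3, 4]),
                                     np.array([2.0, 1, 4, 3]))
        assert res.statistic == pytest.approx(0.6, abs=1e-12)

    def test_zero_variance_flagged(self):
        res = hc.pearson_correlation(np.ones(5), np.arange(5.0))
        assert np.isnan(res.statistic)
        assert res.extra["flag"] == "zero variance"


class TestBenjaminiHochberg:
    def test_monotone_and_bounded(self, rng):
        p = rng.uniform(size=30)
        adj = hc.benjamini_hochberg(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


@pytest.fixture(scope="module")
def tables():
    rng = np.random.default_rng(42)
    fc_rows, ec_rows, score_rows = [], [], []
    pairs = [f"III:{a}-{b}" for a, b in
             (("LPFC", "RPFC"), ("LMC", "RMC"))]
    directed = ["III:LPFC->RPFC", "III:RPFC->LPFC"]
    for g, n in (("hypertension", 5), ("control", 6)):
        for j in range(n):
            sid = f"{g[:3]}{j}"
            for cond in ("resting", "standing"):
                base = 0.4 if g == "control" else 0.3
                fc_rows.append({"subject": sid, "group": g,
                                "condition": cond,
                                **{c: base + 0.03 * rng.standard_normal()
                                   for c in pairs}})
                ec_rows.append({"subject": sid, "group": g,
                                "condition": cond,
                                **{c: base / 3 + 0.02 * rng.standard_normal()
                                   for c in directed}})
            score_rows.append({"subject_id": sid, "group": g,
                               "MMSE": 24 + 3 * (g == "control")
                               + rng.standard_normal(),
                               "MoCA": 23 + 3 * (g == "control")
                               + rng.standard_normal()})
    return (hc.connectivity_table(fc_rows), hc.connectivity_table(ec_rows),
            pd.DataFrame(score_rows))


class TestRunFullStats:
    def test_report_covers_all_analyses(self, tables):
        fc, ec, scores = tables
        df = hc.run_full_stats(fc, ec, scores)
        analyses = set(df["analysis"])
        for name in ("fc_mixed_group", "fc_mixed_condition",
                     "fc_mixed_interaction", "fc_oneway_resting",
                     "fc_oneway_standing", "fc_repeated_hypertension",
                     "fc_repeated_control", "fc_pearson_mmse",
                     "ec_mixed_group", "scores_ttest_mmse",
                     "scores_ttest_moca"):
            assert name in analyses, name
        assert set(df.loc[df["analysis"] == "fc_mixed_group", "connection"]) \
            == {"LPFC-RPFC", "LMC-RMC"}

    def test_group_difference_detected(self, tables):
        fc, ec, scores = tables
        df = hc.run_full_stats(fc, ec, scores)
        oneway = df[df["analysis"] == "fc_oneway_resting"]
        assert (oneway["p"] < 0.05).all()
        t = df[df["analysis"] == "scores_ttest_mmse"]
        assert (t["p"] < 0.05).all()

    def test_bh_correction_columns(self, tables):
        fc, ec, scores = tables
        df = hc.run_full_stats(fc, ec, scores, correction="bh")
        assert "p_bh" in df.columns and "significant_bh" in df.columns
        assert np.all(df["p_bh"] >= df["p"] - 1e-12)


def test_type_one_error_calibration_fast():
    """Null 2x2 mixed tables: each factor's rejection rate stays near the
    nominal 5% (smaller replicate of the full calibration in the acceptance
    suite)."""
    rng = np.random.default_rng(0)
    n1, n2, reps = 13, 16, 300
    rejections = np.zeros(3)
    for _ in range(reps):
        y = rng.standard_normal((n1 + n2, 2)) \
            + rng.standard_normal((n1 + n2, 1))  # subject random effect
        table = make_table([tuple(v) for v in y],
                           ["g1"] * n1 + ["g2"] * n2)
        res = hc.mixed_anova_2x2(table)
        rejections += [res["group"].p < 0.05, res["condition"].p < 0.05,
                       res["interaction"].p < 0.05]
    rates = rejections / reps
    assert np.all(rates > 0.01) and np.all(rates < 0.10)
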