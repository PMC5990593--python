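"""Group-level statistics for connectivity values and cognitive scores.

The statistical layer mirrors a classical two-group, two-condition design:
assumption checks (Kolmogorov–Smirnov against a fitted normal, Levene),
one-way ANOVA between groups within each condition, a 2x2 mixed-design
ANOVA (group as between-subject factor, condition as repeated measure),
repeated-measures comparison of conditions within each group, independent
t-tests on cognitive scores, and Pearson correlation between connectivity
and scores.  Per-connection p-values are reported without multiple-testing
correction by default; Benjamini–Hochberg adjustment is available as an
option.

The 2x2 mixed ANOVA is computed in closed form via the two orthogonal
subject-level contrasts (per-subject mean and per-subject condition
difference), which for a two-level within factor is exactly the classical
mixed-design partition (Type III in the unbalanced-group case; sphericity
is moot with two levels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class TestResult:
    name: str
    statistic: float
    df: tuple[float, ...]
    p: float
    extra: dict | None = None

    def significant(self, alpha: float = 0.05) -> bool:
        return bool(self.p < alpha)


# --------------------------------------------------------------------------
# elementary tests
# --------------------------------------------------------------------------

def assumption_checks(groups: dict[str, np.ndarray]) -> dict[str, TestResult]:
    """Normality (one-sample KS against a normal with the sample's mean and
    SD, per group pooled) and homogeneity of variance (Levene, mean-centred,
    i.e. one-way ANOVA on |x − group mean|)."""
    out: dict[str, TestResult] = {}
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    for v in arrays:
        if v.size < 3:
            raise ValueError("need at least 3 values per group")
    pooled = np.concatenate(arrays)
    ks = sps.kstest(pooled, "norm", args=(pooled.mean(), pooled.std(ddof=1)))
    out["ks"] = TestResult("KS vs fitted normal", float(ks.statistic),
                           (float(pooled.size),), float(ks.pvalue))
    if any(np.ptp(v) == 0 for v in arrays):
        out["levene"] = TestResult("Levene", np.nan,
                                   (np.nan, np.nan), np.nan,
                                   extra={"flag": "constant group"})
    else:
        lev = sps.levene(*arrays, center="mean")
        df1 = len(arrays) - 1
        df2 = pooled.size - len(arrays)
        out["levene"] = TestResult("Levene", float(lev.statistic),
                                   (df1, df2), float(lev.pvalue))
    return out


def one_way_anova(*groups: np.ndarray) -> TestResult:
    """Between-group F = MS_between / MS_within.

    Degenerate separations (zero within-group variance) follow the
    convention F = 0, p = 1 for equal means and F = inf, p = 0 otherwise.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    k = len(arrays)
    n_tot = sum(a.size for a in arrays)
    grand = np.concatenate(arrays).mean()
    ss_b = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_w = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df1, df2 = k - 1, n_tot - k
    if ss_w == 0:
        if ss_b == 0:
            return TestResult("one-way ANOVA", 0.0, (df1, df2), 1.0)
        return TestResult("one-way ANOVA", np.inf, (df1, df2), 0.0)
    f = (ss_b / df1) / (ss_w / df2)
    p = float(sps.f.sf(f, df1, df2))
    return TestResult("one-way ANOVA", float(f), (df1, df2), p)


def _two_sample_f(x1: np.ndarray, x2: np.ndarray, name: str) -> TestResult:
    """Pooled two-sample t expressed as F = t² on (1, n1 + n2 − 2) df."""
    n1, n2 = x1.size, x2.size
    df = n1 + n2 - 2
    sp2 = (((x1 - x1.mean()) ** 2).sum() + ((x2 - x2.mean()) ** 2).sum()) / df
    diff = x1.mean() - x2.mean()
    if sp2 == 0:
        if diff == 0:
            return TestResult(name, 0.0, (1, df), 1.0)
        return TestResult(name, np.inf, (1, df), 0.0)
    f = diff ** 2 / (sp2 * (1 / n1 + 1 / n2))
    return TestResult(name, float(f), (1, df), float(sps.f.sf(f, 1, df)))


def mixed_anova_2x2(table: pd.DataFrame,
                    value: str = "value",
                    subject: str = "subject",
                    group: str = "group",
                    condition: str = "condition"
                    ) -> dict[str, TestResult]:
    """Two-way mixed ANOVA: group (between) x condition (2-level repeated).

    ``table`` is long-format with one row per subject x condition; every
    subject must have both conditions.  Returns TestResults for the group
    main effect, the condition main effect and their interaction, each on
    (1, N − 2) df where N is the number of subjects.
    """
    conds = sorted(table[condition].unique())
    if len(conds) != 2:
        raise ValueError("exactly two conditions required")
    wide = table.pivot_table(index=[subject, group], columns=condition,
                             values=value, aggfunc="first")
    if wide[conds].isna().any().any():
        raise ValueError("every subject needs both conditions")
    wide = wide.reset_index()
    glabels = sorted(wide[group].unique())
    if len(glabels) != 2:
        raise ValueError("exactly two groups required")
    means, diffs = [], []
    for g in glabels:
        sub = wide[wide[group] == g]
        means.append(((sub[conds[0]] + sub[conds[1]]) / 2).to_numpy())
        diffs.append((sub[conds[1]] - sub[conds[0]]).to_numpy())
    n1, n2 = means[0].size, means[1].size
    df_err = n1 + n2 - 2

    out = {"group": _two_sample_f(means[0], means[1], "mixed ANOVA: group")}

    # condition main effect: unweighted mean of the two group mean
    # differences against the pooled within-group variance of the difference
    d1, d2 = diffs
    est = 0.5 * (d1.mean() + d2.mean())
    sp2 = (((d1 - d1.mean()) ** 2).sum() + ((d2 - d2.mean()) ** 2).sum()) / df_err
    if sp2 == 0:
        fc = 0.0 if est == 0 else np.inf
        pc = 1.0 if est == 0 else 0.0
    else:
        fc = est ** 2 / (sp2 * (1 / n1 + 1 / n2) / 4)
        pc = float(sps.f.sf(fc, 1, df_err))
    out["condition"] = TestResult("mixed ANOVA: condition", float(fc),
                                  (1, df_err), pc)
    out["interaction"] = _two_sample_f(d1, d2, "mixed ANOVA: interaction")
    return out


def repeated_measures_comparison(resting: np.ndarray,
                                 standing: np.ndarray) -> TestResult:
    """One-way repeated-measures ANOVA over the two conditions, paired by
    subject; equivalent to the paired t-test via F = t²."""
    x = np.asarray(resting, dtype=float)
    y = np.asarray(standing, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    d = y - x
    n = d.size
    var = d.var(ddof=1)
    if var == 0:
        if d.mean() == 0:
            return TestResult("repeated measures", 0.0, (1, n - 1), 1.0)
        return TestResult("repeated measures", np.inf, (1, n - 1), 0.0)
    f = d.mean() ** 2 / (var / n)
    return TestResult("repeated measures", float(f), (1, n - 1),
                      float(sps.f.sf(f, 1, n - 1)))


def independent_t_test(group1: np.ndarray, group2: np.ndarray) -> TestResult:
    """Pooled-variance two-sample t, two-sided."""
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 values per group")
    df = x.size + y.size - 2
    sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / df
    if sp2 == 0:
        if x.mean() == y.mean():
            return TestResult("t-test", 0.0, (df,), 1.0)
        return TestResult("t-test", np.inf * np.sign(x.mean() - y.mean()),
                          (df,), 0.0)
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / x.size + 1 / y.size))
    p = float(2 * sps.t.sf(abs(t), df))
    return TestResult("t-test", float(t), (df,), p)


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Pearson r with the usual t-based two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of >= 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult("Pearson r", np.nan, (float(x.size - 2),), np.nan,
                          extra={"flag": "zero variance"})
    r, p = sps.pearsonr(x, y)
    return TestResult("Pearson r", float(r), (float(x.size - 2),), float(p))


# --------------------------------------------------------------------------
# full reporting layer
# --------------------------------------------------------------------------

def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (step-up)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def connectivity_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble per-recording connectivity values into a subject x condition
    table.  Each row dict carries subject/group/condition plus one column per
    ``band:connection`` identifier."""
    df = pd.DataFrame(rows)
    meta = ["subject", "group", "condition"]
    return df[meta + [c for c in df.columns if c not in meta]]


def _connection_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns
            if c not in ("subject", "group", "condition")]


def run_full_stats(fc: pd.DataFrame | None,
                   ec: pd.DataFrame | None,
                   scores: pd.DataFrame | None = None,
                   alpha: float = 0.05,
                   correlate_group: str | None = None,
                   correlate_condition: str = "resting",
                   correction: str | None = None) -> pd.DataFrame:
    """The full statistical report for a study.

    For every connection x band column: the 2x2 mixed ANOVA, per-condition
    one-way ANOVA between groups, and per-group repeated-measures comparison
    of conditions.  Cognitive scores get independent t-tests between groups,
    and each connection's value (``correlate_condition``, within
    ``correlate_group``; default the first group label) is correlated with
    MMSE and MoCA.  ``correction="bh"`` adds Benjamini–Hochberg-adjusted
    p-values per analysis family.
    """
    records = []

    def add(analysis, band, connection, res: TestResult, **extra):
        stat = res.statistic
        records.append({
            "analysis": analysis, "band": band, "connection": connection,
            "statistic": res.name, "value": stat,
            "df1": res.df[0], "df2": res.df[1] if len(res.df) > 1 else np.nan,
            "p": res.p, **extra})

    for name, table in (("fc", fc), ("ec", ec)):
        if table is None:
            continue
        groups = sorted(table["group"].unique())
        conditions = sorted(table["condition"].unique())
        for col in _connection_columns(table):
            band, connection = col.split(":", 1)
            long = table[["subject", "group", "condition", col]].rename(
                columns={col: "value"})
            mixed = mixed_anova_2x2(long)
            for factor, res in mixed.items():
                add(f"{name}_mixed_{factor}", band, connection, res)
            for cond in conditions:
                sub = long[long["condition"] == cond]
                vals = [sub[sub["group"] == g]["value"].to_numpy()
                        for g in groups]
                add(f"{name}_oneway_{cond}", band, connection,
                    one_way_anova(*vals))
            for g in groups:
                sub = long[long["group"] == g].pivot_table(
                    index="subject", columns="condition", values="value")
                add(f"{name}_repeated_{g}", band, connection,
                    repeated_measures_comparison(
                        sub[conditions[0]].to_numpy(),
                        sub[conditions[1]].to_numpy()))
            if scores is not None:
                cg = correlate_group or groups[0]
                sub = long[(long["group"] == cg)
                           & (long["condition"] == correlate_condition)]
                merged = sub.merge(scores, left_on="subject",
                                   right_on="subject_id")
                for score in ("MMSE", "MoCA"):
                    add(f"{name}_pearson_{score.lower()}", band, connection,
                        pearson_correlation(merged["value"].to_numpy(),
                                            merged[score].to_numpy()))

    if scores is not None:
        glabels = sorted(scores["group"].unique())
        for score in ("MMSE", "MoCA"):
            vals = [scores[scores["group"] == g][score].to_numpy()
                    for g in glabels]
            add(f"scores_ttest_{score.lower()}", "", score,
                independent_t_test(*vals))

    df = pd.DataFrame.from_records(records)
    df["significant"] = (df["p"] < alpha).astype(int)
    if correction == "bh":
        df["p_bh"] = np.nan
        for analysis, idx in df.groupby("analysis").groups.items():
            df.loc[idx, "p_bh"] = benjamini_hochberg(df.loc[idx, "p"].to_numpy())
        df["significant_bh"] = (df["p_bh"] < alpha).astype(int)
    return df
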