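"""Hypothesis tests used throughout the pipeline.

The tests mirror a classical behavioural-pharmacology report: pooled-variance
Student's t, one-way ANOVA, a two-way mixed-design (repeated-measures)
ANOVA with the textbook univariate error partition, Bonferroni post hoc
adjustment, Benjamini-Hochberg FDR adjustment, and Pearson's chi-square on
contingency tables.  Statistics and sums of squares are computed from first
principles; only the reference distributions (t, F, chi2) come from scipy.

The mixed ANOVA is the workhorse: one between-subject factor (sex or
behavioural cluster) crossed with one within-subject factor (substance or
day), every subject measured once at every within level.  Its degrees of
freedom follow the design identities

    group:        (g - 1,  N - g)
    within:       (a - 1,  (a - 1)(N - g))
    interaction:  ((a - 1)(g - 1), (a - 1)(N - g))

with a = number of within levels, g = number of groups, N = number of
subjects.  No sphericity correction is applied: reported df are the
uncorrected integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "MixedAnovaResult",
    "DegenerateTableError",
    "t_test",
    "oneway_anova",
    "mixed_rm_anova",
    "posthoc_bonferroni",
    "bh_adjust",
    "chi_square_test",
]


class DegenerateTableError(ValueError):
    """Contingency table with fewer than two informative rows or columns."""


@dataclass
class TestResult:
    """A single test statistic with its reference distribution bookkeeping.

    ``df`` is an int for t / chi-square, a ``(df_num, df_den)`` pair for F.
    ``group_stats`` maps group label -> (mean, sem, n) for the "mean +/- SEM"
    reporting convention.
    """

    name: str
    statistic: float
    df: tuple[int, int] | int
    p: float
    group_stats: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "test": self.name,
            "statistic": float(self.statistic),
            "df": list(self.df) if isinstance(self.df, tuple) else int(self.df),
            "p": float(self.p),
            "group_stats": {
                str(k): {"mean": float(m), "sem": float(s), "n": int(n)}
                for k, (m, s, n) in self.group_stats.items()
            },
        }


@dataclass
class MixedAnovaResult:
    """Effect rows of a two-way mixed-design ANOVA plus its error terms."""

    effects: dict  # name -> TestResult with F and (df_num, df_den)
    ss: dict  # sums of squares by component
    ms_error_between: float  # subjects-within-groups mean square
    ms_error_within: float  # residual (within x subject) mean square
    df_error_between: int
    df_error_within: int
    cell_means: pd.DataFrame  # group x within level -> mean, sem, n
    n_subjects: int
    n_groups: int
    n_within: int

    def to_dict(self) -> dict:
        return {
            "effects": {k: v.to_dict() for k, v in self.effects.items()},
            "ss": {k: float(v) for k, v in self.ss.items()},
            "n_subjects": self.n_subjects,
            "n_groups": self.n_groups,
            "n_within": self.n_within,
        }


def _mean_sem_n(x: np.ndarray) -> tuple[float, float, int]:
    x = np.asarray(x, dtype=float)
    n = x.size
    sem = float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return float(np.mean(x)), sem, n


def t_test(x, y) -> TestResult:
    """Two-tailed pooled-variance (Student's) two-sample t test.

    df = n1 + n2 - 2.  Identical inputs give t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("t_test requires n >= 2 in each group")
    n1, n2 = x.size, y.size
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / df
    se = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    diff = np.mean(x) - np.mean(y)
    if se == 0.0:
        t = 0.0 if diff == 0.0 else np.inf * np.sign(diff)
    else:
        t = diff / se
    p = float(2.0 * sps.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return TestResult(
        name="t",
        statistic=float(t),
        df=int(df),
        p=min(1.0, p),
        group_stats={"x": _mean_sem_n(x), "y": _mean_sem_n(y)},
    )


def oneway_anova(groups) -> TestResult:
    """One-way fixed-effects ANOVA; F = MS_between / MS_within, df (g-1, N-g).

    ``groups`` is a sequence of 1-D samples.  Constant data give F = 0.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("oneway_anova requires >= 2 groups")
    if any(a.size < 1 for a in arrays):
        raise ValueError("every group must be non-empty")
    all_vals = np.concatenate(arrays)
    n_total = all_vals.size
    g = len(arrays)
    df_b, df_w = g - 1, n_total - g
    if df_w < 1:
        raise ValueError("no within-group degrees of freedom")
    grand = all_vals.mean()
    ss_b = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_w = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    ms_b, ms_w = ss_b / df_b, ss_w / df_w
    if ms_w == 0.0:
        f = 0.0 if np.isclose(ss_b, 0.0) else np.inf
    else:
        f = ms_b / ms_w
    p = float(sps.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0
    return TestResult(
        name="F",
        statistic=float(f),
        df=(int(df_b), int(df_w)),
        p=p,
        group_stats={i: _mean_sem_n(a) for i, a in enumerate(arrays)},
    )


def _check_balanced(data: pd.DataFrame, subject: str, within: str, group: str) -> None:
    levels = data[within].unique()
    a = len(levels)
    counts = data.groupby(subject, observed=True)[within].agg(["count", "nunique"])
    bad = counts.index[(counts["count"] != a) | (counts["nunique"] != a)].tolist()
    if bad:
        raise ValueError(
            f"unbalanced design: subjects not observed exactly once at every "
            f"within level: {bad}"
        )
    g_per_subj = data.groupby(subject, observed=True)[group].nunique()
    multi = g_per_subj.index[g_per_subj > 1].tolist()
    if multi:
        raise ValueError(f"subjects assigned to more than one group: {multi}")


def mixed_rm_anova(
    data: pd.DataFrame,
    subject: str = "subject",
    group: str = "group",
    within: str = "within",
    value: str = "value",
) -> MixedAnovaResult:
    """Two-way mixed-design ANOVA from a long table.

    Classical univariate partition: between-subject SS splits into the group
    effect and subjects-within-groups (the error term for the group effect);
    within-subject SS splits into the within factor, the interaction, and the
    residual (the error term for both).  Requires a balanced within factor
    (every subject at every level exactly once); group sizes may differ, in
    which case marginal within-level means are subject-weighted.
    """
    data = data[[subject, group, within, value]].copy()
    if data[value].isna().any():
        raise ValueError("missing values in the response column")
    _check_balanced(data, subject, within, group)

    y = data[value].to_numpy(dtype=float)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    subj_means = data.groupby(subject, observed=True)[value].mean()
    subj_group = data.groupby(subject, observed=True)[group].first()
    group_sizes = subj_group.value_counts()
    n_subjects = len(subj_means)
    a = data[within].nunique()
    g = len(group_sizes)
    if g < 2 or a < 2:
        raise ValueError("need >= 2 groups and >= 2 within levels")

    # Between-subject stratum.
    ss_between_subj = float(a * ((subj_means - grand) ** 2).sum())
    group_means = subj_means.groupby(subj_group).mean()
    ss_group = float(
        a * sum(group_sizes[gr] * (group_means[gr] - grand) ** 2 for gr in group_means.index)
    )
    ss_subj = ss_between_subj - ss_group

    # Within-subject stratum (weighted marginal means under unequal n_g).
    level_means = data.groupby(within, observed=True)[value].mean()
    ss_within_factor = float(n_subjects * ((level_means - grand) ** 2).sum())
    cell = data.groupby([group, within], observed=True)[value].agg(["mean", "count"])
    ss_cells = float((cell["count"] * (cell["mean"] - grand) ** 2).sum())
    ss_inter = max(0.0, ss_cells - ss_group - ss_within_factor)
    ss_resid = max(0.0, ss_total - ss_between_subj - ss_within_factor - ss_inter)

    df_group, df_err_b = g - 1, n_subjects - g
    df_within = a - 1
    df_inter = (a - 1) * (g - 1)
    df_err_w = (a - 1) * (n_subjects - g)
    ms_err_b = ss_subj / df_err_b
    ms_err_w = ss_resid / df_err_w

    def f_row(name: str, ss_eff: float, df_num: int, ms_err: float, df_den: int) -> TestResult:
        ms_eff = ss_eff / df_num
        if ms_err == 0.0:
            f = 0.0 if np.isclose(ss_eff, 0.0) else np.inf
        else:
            f = ms_eff / ms_err
        p = float(sps.f.sf(f, df_num, df_den)) if np.isfinite(f) else 0.0
        return TestResult(name=name, statistic=float(f), df=(int(df_num), int(df_den)), p=p)

    effects = {
        "group": f_row("F", ss_group, df_group, ms_err_b, df_err_b),
        "within": f_row("F", ss_within_factor, df_within, ms_err_w, df_err_w),
        "interaction": f_row("F", ss_inter, df_inter, ms_err_w, df_err_w),
    }
    cell_stats = (
        data.groupby([group, within], observed=True)[value]
        .agg(mean="mean", sem=lambda s: s.sem() if len(s) > 1 else 0.0, n="count")
        .reset_index()
    )
    return MixedAnovaResult(
        effects=effects,
        ss={
            "total": ss_total,
            "group": ss_group,
            "subjects_within_groups": ss_subj,
            "within": ss_within_factor,
            "interaction": ss_inter,
            "residual": ss_resid,
        },
        ms_error_between=float(ms_err_b),
        ms_error_within=float(ms_err_w),
        df_error_between=int(df_err_b),
        df_error_within=int(df_err_w),
        cell_means=cell_stats,
        n_subjects=int(n_subjects),
        n_groups=int(g),
        n_within=int(a),
    )


def posthoc_bonferroni(
    data: pd.DataFrame,
    fit: MixedAnovaResult,
    contrasts: list[tuple],
    subject: str = "subject",
    group: str = "group",
    within: str = "within",
    value: str = "value",
) -> list[dict]:
    """Bonferroni-adjusted pairwise contrasts after :func:`mixed_rm_anova`.

    Each contrast is ``("group", g1, g2)`` (group marginal means, error =
    subjects-within-groups MS on the subject-mean scale) or
    ``("within", l1, l2)`` (within-level marginal means, error = residual MS).
    p_adj = min(1, m * p) with m = family size.
    """
    if not contrasts:
        raise ValueError("empty contrast family")
    m = len(contrasts)
    subj_means = data.groupby(subject, observed=True)[value].mean()
    subj_group = data.groupby(subject, observed=True)[group].first()
    a = fit.n_within
    out = []
    for kind, lv1, lv2 in contrasts:
        if kind == "group":
            x1 = subj_means[subj_group == lv1]
            x2 = subj_means[subj_group == lv2]
            # subject means average a correlated observations: their error
            # variance is MS_subj(group) / a on this scale
            se = np.sqrt((fit.ms_error_between / a) * (1.0 / len(x1) + 1.0 / len(x2)))
            df = fit.df_error_between
            diff = x1.mean() - x2.mean()
        elif kind == "within":
            w = data.set_index([subject, within])[value]
            x1 = w.xs(lv1, level=within)
            x2 = w.xs(lv2, level=within)
            se = np.sqrt(fit.ms_error_within * (1.0 / len(x1) + 1.0 / len(x2)))
            df = fit.df_error_within
            diff = x1.mean() - x2.mean()
        else:
            raise ValueError(f"unknown contrast kind {kind!r}")
        t = 0.0 if se == 0.0 and diff == 0.0 else (np.inf if se == 0.0 else diff / se)
        p = float(2.0 * sps.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
        out.append(
            {
                "kind": kind,
                "level_1": lv1,
                "level_2": lv2,
                "diff": float(diff),
                "t": float(t),
                "df": int(df),
                "p": min(1.0, p),
                "p_adj": min(1.0, m * p),
            }
        )
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def chi_square_test(table) -> TestResult:
    """Pearson chi-square of independence on an r x c count table.

    Rows/columns whose total is zero are dropped (their expected counts are
    undefined); no continuity correction.  df = (r - 1)(c - 1) on the kept
    table; p is the upper tail of the chi-square distribution.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("table must be 2-D")
    if np.any(t < 0) or np.any(np.isnan(t)):
        raise ValueError("counts must be nonnegative")
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    r, c = t.shape
    if r < 2 or c < 2:
        raise DegenerateTableError(
            f"need >= 2 informative rows and columns, got {r} x {c}"
        )
    row = t.sum(axis=1, keepdims=True)
    col = t.sum(axis=0, keepdims=True)
    expected = row @ col / t.sum()
    chi2 = float(((t - expected) ** 2 / expected).sum())
    df = (r - 1) * (c - 1)
    return TestResult(
        name="chi2", statistic=chi2, df=int(df), p=float(sps.chi2.sf(chi2, df))
    )
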