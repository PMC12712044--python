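"""Normality-gated group comparisons for feature tables.

Each contrast (cardiac phase, sex, age group, myocardial region) is tested
per feature with the classical decision rule: Shapiro-Wilk normality on
every group (on within-subject differences for paired designs); if all
normality p-values are >= the gate alpha the parametric test is used
(paired/independent t, one-way ANOVA), otherwise its nonparametric
counterpart (Wilcoxon signed-rank, Mann-Whitney U, Kruskal-Wallis).
Significance is two-tailed at alpha = 0.05.  For more than two groups,
pairwise post-hoc p-values are Bonferroni-adjusted and capped at 1.0.

The t tests and ANOVA are the classical equal-variance forms (a Welch
switch is provided but off by default, mirroring common clinical-stats
practice of the era this workflow models).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "choose_test",
    "run_test",
    "compare",
    "correlation_strength",
    "TestResult",
]

ALPHA = 0.05
NORMALITY_ALPHA = 0.05

PARAMETRIC = {"paired": "paired_t", "independent": "indep_t", "k_groups": "anova"}
NONPARAMETRIC = {
    "paired": "wilcoxon",
    "independent": "mann_whitney",
    "k_groups": "kruskal_wallis",
}


def _degenerate(groups) -> bool:
    return any(np.unique(g).size < 2 for g in groups)


def choose_test(samples, design: str) -> str:
    """Pick the test branch for a contrast by Shapiro-Wilk gating.

    ``samples`` is a list of per-group value arrays (two equal-length
    arrays for a paired design).  Degenerate or too-small groups fall back
    to the nonparametric branch with a warning.
    """
    if design not in PARAMETRIC:
        raise ValueError(f"unknown design {design!r}")
    groups = [np.asarray(s, dtype=np.float64) for s in samples]
    if any(g.size < 3 for g in groups):
        warnings.warn("group too small for Shapiro-Wilk; nonparametric fallback",
                      stacklevel=2)
        return NONPARAMETRIC[design]
    if design == "paired":
        if len(groups) != 2 or groups[0].size != groups[1].size:
            raise ValueError("paired design needs two equal-length samples")
        groups = [groups[0] - groups[1]]
    if _degenerate(groups):
        warnings.warn("degenerate (constant) data; nonparametric fallback",
                      stacklevel=2)
        return NONPARAMETRIC[design]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pvals = [stats.shapiro(g).pvalue for g in groups]
    if all(p >= NORMALITY_ALPHA for p in pvals):
        return PARAMETRIC[design]
    return NONPARAMETRIC[design]


def run_test(samples, test: str, welch: bool = False) -> float:
    """Two-tailed p-value of a named test branch on per-group samples."""
    g = [np.asarray(s, dtype=np.float64) for s in samples]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if test == "paired_t":
            return float(stats.ttest_rel(g[0], g[1]).pvalue)
        if test == "wilcoxon":
            if np.all(g[0] == g[1]):
                return 1.0  # no signed ranks: no evidence of a difference
            return float(stats.wilcoxon(g[0], g[1]).pvalue)
        if test == "indep_t":
            return float(stats.ttest_ind(g[0], g[1], equal_var=not welch).pvalue)
        if test == "mann_whitney":
            return float(stats.mannwhitneyu(g[0], g[1],
                                            alternative="two-sided").pvalue)
        if test == "anova":
            return float(stats.f_oneway(*g).pvalue)
        if test == "kruskal_wallis":
            if _degenerate(g) and np.unique(np.concatenate(g)).size < 2:
                return 1.0
            return float(stats.kruskal(*g).pvalue)
    raise ValueError(f"unknown test {test!r}")


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value, capped at exactly 1.0."""
    return float(min(1.0, p * m))


@dataclass
class TestResult:
    feature: str
    contrast: str
    test_used: str
    p_value: float
    significant: bool
    summaries: dict[str, tuple[float, float, int]]  # group -> (mean, SD, n)
    posthoc: dict[str, float] = field(default_factory=dict)


def compare(
    table: pd.DataFrame,
    contrast: str,
    design: str,
    features=None,
    subject_col: str = "subject_id",
    welch: bool = False,
) -> pd.DataFrame:
    """Per-feature group comparison report for one contrast column.

    ``table`` is long-per-subject wide-per-feature: one row per
    (subject, contrast level), a column named ``contrast`` with the group
    label, and one column per feature.  Paired designs match rows by
    ``subject_col``.  Returns one row per feature with the chosen test,
    p-value, significance at alpha = 0.05, per-group "mean +/- SD (n)"
    summaries and, for k > 2 groups, Bonferroni-adjusted pairwise
    p-values (capped at 1.0).
    """
    levels = [lv for lv in pd.unique(table[contrast])]
    if len(levels) < 2:
        raise ValueError("contrast needs at least two levels")
    if design != "k_groups" and len(levels) != 2:
        raise ValueError("two-level design with != 2 levels")
    if features is None:
        features = [c for c in table.columns
                    if c not in (contrast, subject_col)
                    and pd.api.types.is_numeric_dtype(table[c])]

    rows = []
    for f in features:
        if design == "paired":
            wide = table.pivot_table(index=subject_col, columns=contrast,
                                     values=f, aggfunc="first").dropna()
            groups = [wide[lv].to_numpy() for lv in levels]
        else:
            groups = [table.loc[table[contrast] == lv, f]
                      .dropna().to_numpy() for lv in levels]
        ns = [g.size for g in groups]
        if min(ns) < 3:
            warnings.warn(f"feature {f!r}: too few complete values", stacklevel=2)
            rows.append([f, contrast, "none", np.nan, False]
                        + _summaries(groups, levels) + [np.nan] * _n_pairs(levels))
            continue
        test = choose_test(groups, design)
        p = run_test(groups, test, welch=welch)
        row = [f, contrast, test, p, bool(p < ALPHA)]
        row += _summaries(groups, levels)
        if design == "k_groups":
            m = _n_pairs(levels)
            pair_design = "independent"
            for i in range(len(levels)):
                for j in range(i + 1, len(levels)):
                    sub = [groups[i], groups[j]]
                    t2 = choose_test(sub, pair_design)
                    row.append(bonferroni(run_test(sub, t2, welch=welch), m))
        rows.append(row)

    cols = ["feature", "contrast", "test_used", "p_value", "significant"]
    for lv in levels:
        cols += [f"mean[{lv}]", f"sd[{lv}]", f"n[{lv}]"]
    if design == "k_groups":
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                cols.append(f"p[{levels[i]} vs {levels[j]}]")
    return pd.DataFrame(rows, columns=cols).set_index("feature")


def _n_pairs(levels) -> int:
    k = len(levels)
    return k * (k - 1) // 2


def _summaries(groups, levels) -> list:
    out = []
    for g in groups:
        if g.size:
            out += [float(np.mean(g)), float(np.std(g, ddof=1)) if g.size > 1
                    else 0.0, int(g.size)]
        else:
            out += [np.nan, np.nan, 0]
    return out


def correlation_strength(r: float) -> str:
    """Bin |r|: < 0.5 low, [0.5, 0.8) intermediate, >= 0.8 strong."""
    if not (-1.0 <= r <= 1.0):
        raise ValueError("r must be in [-1, 1]")
    a = abs(r)
    if a < 0.5:
        return "low"
    if a < 0.8:
        return "intermediate"
    return "strong"
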