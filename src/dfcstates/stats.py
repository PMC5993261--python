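"""Group-level statistics: reliability, group contrasts, correlations.

Covers the study-style analyses downstream of the state and graph
metrics: test-retest (run 1 vs. run 2) Pearson reliability of each
metric per group, Welch two-sample comparisons of group means,
the chi-square test on the group x dominant-state contingency table,
and predictor x outcome correlation tables (raw p-values, optional
Benjamini-Hochberg column — never silently adjusted).
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "pearson_r", "testretest_report", "dominant_state",
    "dominant_state_test", "correlation_table", "group_mean_compare",
]


def pearson_r(x, y):
    """Product-moment correlation with pairwise deletion.

    Returns ``(r, p, n)``; p is two-sided from the t transform with
    n - 2 df. Zero variance in either vector yields ``(nan, nan, n)``
    with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = int(x.size)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero variance; correlation undefined", RuntimeWarning,
                      stacklevel=2)
        return float("nan"), float("nan"), n
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n


def testretest_report(metrics_run1: pd.DataFrame, metrics_run2: pd.DataFrame,
                      group_map: dict, pooled: bool = True) -> pd.DataFrame:
    """Run 1 vs. run 2 reliability of every metric column, per group.

    Inputs are subject-indexed DataFrames with one column per metric
    (e.g. per-state frequencies, transition count, mean PL/CC).
    Subjects missing either run are dropped (count logged in ``n``).
    With ``pooled=True`` an across-cohort row ("all") is included per
    metric.
    """
    common = metrics_run1.index.intersection(metrics_run2.index)
    if len(common) == 0:
        raise ValueError("no subjects present in both runs")
    m1 = metrics_run1.loc[common]
    m2 = metrics_run2.loc[common]
    groups = pd.Series({s: group_map[s] for s in common})
    rows = []
    group_values = sorted(set(groups))
    scopes = ([("all", np.ones(len(common), dtype=bool))] if pooled else []) \
        + [(g, (groups == g).to_numpy()) for g in group_values]
    for metric in metrics_run1.columns:
        for gname, sel in scopes:
            x = m1.loc[sel.tolist(), metric]
            y = m2.loc[sel.tolist(), metric]
            if sel.sum() < 3:
                continue
            try:
                r, p, n = pearson_r(x, y)
            except ValueError:
                continue
            rows.append({"group": gname, "metric": metric,
                         "r": r, "p": p, "n": n})
    return pd.DataFrame(rows)


def dominant_state_test(dominant_state: pd.Series, group_map: dict):
    """Pearson chi-square on the group x dominant-state table.

    ``dominant_state`` maps subject -> 1-based dominant state id (the
    state with maximal frequency; upstream ties are broken to the
    lowest id). Returns ``(chi2, df, p, table, expected, small_cells)``
    where ``small_cells`` is True when any expected count < 5.
    """
    groups = pd.Series({s: group_map[s] for s in dominant_state.index})
    if groups.nunique() < 2:
        raise ValueError("need at least 2 groups")
    counts = groups.value_counts()
    if (counts == 0).any():
        raise ValueError("every group needs at least one subject")
    table = pd.crosstab(groups, dominant_state)
    res = stats.chi2_contingency(table.to_numpy(), correction=False)
    small = bool((res.expected_freq < 5).any())
    if small:
        warnings.warn("expected count < 5 in the contingency table; "
                      "chi-square approximation may be poor", RuntimeWarning,
                      stacklevel=2)
    return (float(res.statistic), int(res.dof), float(res.pvalue), table,
            res.expected_freq, small)


def dominant_state(frequencies: pd.DataFrame) -> pd.Series:
    """Per-subject dominant state from a subject x state frequency table.

    Ties are broken to the lowest state id (deterministic; logged via
    warning when any occur). Columns must be 1-based state ids.
    """
    F = frequencies.to_numpy(dtype=float)
    ids = np.asarray(frequencies.columns)
    best = F.argmax(axis=1)  # argmax takes first (lowest) on ties
    n_ties = int(sum((F[i] == F[i, best[i]]).sum() > 1 for i in range(len(F))))
    if n_ties:
        warnings.warn(f"{n_ties} subject(s) had tied dominant states; "
                      "ties broken to the lowest state id", RuntimeWarning,
                      stacklevel=2)
    return pd.Series(ids[best], index=frequencies.index,
                     name="dominant_state")


def correlation_table(predictors: pd.DataFrame, outcomes: pd.DataFrame,
                      bh_adjust: bool = False) -> pd.DataFrame:
    """Tidy r/p/n table for every predictor x outcome pair.

    Raw correlations only — no sign convention is imposed on "better"
    scores. With ``bh_adjust`` a Benjamini-Hochberg ``p_bh`` column is
    appended across the whole table.
    """
    common = predictors.index.intersection(outcomes.index)
    rows = []
    for pcol in predictors.columns:
        for ocol in outcomes.columns:
            r, p, n = pearson_r(predictors.loc[common, pcol],
                                outcomes.loc[common, ocol])
            rows.append({"predictor": pcol, "outcome": ocol,
                         "r": r, "p": p, "n": n})
    df = pd.DataFrame(rows)
    if bh_adjust and len(df):
        ok = df["p"].notna()
        padj = np.full(len(df), np.nan)
        if ok.any():
            padj[ok.to_numpy()] = multipletests(
                df.loc[ok, "p"], method="fdr_bh")[1]
        df["p_bh"] = padj
    return df


def group_mean_compare(values: pd.Series, group_map: dict) -> dict:
    """Welch two-sample comparison of a per-subject metric.

    Returns a dict with per-group means/SDs/ns and the Welch t and
    two-sided p. Requires exactly two groups with >= 2 subjects each.
    """
    groups = pd.Series({s: group_map[s] for s in values.index})
    names = sorted(set(groups))
    if len(names) != 2:
        raise ValueError("group_mean_compare expects exactly 2 groups")
    a = values[groups == names[0]].to_numpy(dtype=float)
    b = values[groups == names[1]].to_numpy(dtype=float)
    if min(a.size, b.size) < 2:
        raise ValueError("each group needs at least 2 subjects")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {
        "groups": names,
        "mean": {names[0]: float(a.mean()), names[1]: float(b.mean())},
        "sd": {names[0]: float(a.std(ddof=1)), names[1]: float(b.std(ddof=1))},
        "n": {names[0]: int(a.size), names[1]: int(b.size)},
        "t": float(t), "p": float(p),
    }
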