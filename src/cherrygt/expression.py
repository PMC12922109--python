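"""Relative qPCR expression by 2^-ddCt with ANOVA + Tukey HSD comparison.

Per sample, dCt = target Ct - reference Ct; ddCt subtracts the
calibrator group's mean dCt (Livak convention), and relative expression
is 2^-ddCt, so the calibrator group averages 1 in the noiseless case.
Group differences are tested on the expression scale by default (as the
values are usually plotted), one-way ANOVA followed by Tukey's HSD with
a compact-letter display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

CT_PLAUSIBLE = (10.0, 40.0)


def delta_delta_ct(records: pd.DataFrame, calibrator_group: str) -> pd.DataFrame:
    """Per-sample relative expression from a Ct table.

    ``records`` needs columns ``sample_id, group, target_ct,
    reference_ct``.  Rows with a missing reference Ct are skipped with a
    warning; Ct values outside the plausible qPCR range (10-40) warn but
    are kept.  Adds columns ``delta_ct, delta_delta_ct, rel_expr``.
    """
    df = records.copy()
    missing = df["reference_ct"].isna() | df["target_ct"].isna()
    if missing.any():
        warnings.warn(f"skipping {int(missing.sum())} record(s) with missing Ct",
                      stacklevel=2)
        df = df[~missing]
    if calibrator_group not in set(df["group"]):
        raise ValueError(f"calibrator group {calibrator_group!r} has no records")
    cts = df[["target_ct", "reference_ct"]].to_numpy(dtype=float)
    lo, hi = CT_PLAUSIBLE
    if ((cts < lo) | (cts > hi)).any():
        warnings.warn(f"Ct values outside the plausible range {lo}-{hi}", stacklevel=2)
    df["delta_ct"] = df["target_ct"] - df["reference_ct"]
    calib_mean = df.loc[df["group"] == calibrator_group, "delta_ct"].mean()
    df["delta_delta_ct"] = df["delta_ct"] - calib_mean
    df["rel_expr"] = 2.0 ** (-df["delta_delta_ct"])
    return df


@dataclass
class ExpressionTest:
    f_statistic: float
    p_value: float
    tukey: pd.DataFrame        # pairwise comparisons with adjusted p
    letters: dict[str, str]    # compact-letter display per group


def _compact_letters(groups: list[str], significant: set[frozenset[str]]) -> dict[str, str]:
    """Insert-and-absorb compact-letter display.

    Start from one set holding every group; for each significantly
    different pair, split any set containing both; drop subsets; letter
    the surviving sets in order of first group appearance.
    """
    sets: list[set[str]] = [set(groups)]
    for pair in significant:
        a, b = tuple(pair)
        new_sets = []
        for s in sets:
            if a in s and b in s:
                new_sets.extend([s - {a}, s - {b}])
            else:
                new_sets.append(s)
        # absorb: drop sets contained in another
        sets = [s for s in new_sets
                if s and not any(s < t for t in new_sets)]
        # dedupe
        uniq = []
        for s in sets:
            if s not in uniq:
                uniq.append(s)
        sets = uniq
    order = {g: i for i, g in enumerate(groups)}
    sets.sort(key=lambda s: min(order[g] for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for i, s in enumerate(sets):
        for g in s:
            letters[g] += alphabet[i]
    return letters


def anova_tukey(values: pd.DataFrame, value_col: str = "rel_expr",
                group_col: str = "group", alpha: float = 0.05) -> ExpressionTest:
    """One-way ANOVA followed by Tukey HSD and a compact-letter display.

    Groups sharing no letter differ at the chosen alpha, matching the
    lowercase-letter annotation convention of expression bar plots.
    """
    groups = list(dict.fromkeys(values[group_col]))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [values.loc[values[group_col] == g, value_col].to_numpy(dtype=float)
              for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least two observations")
    if np.ptp(np.concatenate(arrays)) == 0:
        # all observations identical: F = 0 by definition, nothing to separate
        f_stat, p = 0.0, 1.0
        tukey_df = pd.DataFrame(
            [(a, b, 0.0, 1.0, False) for i, a in enumerate(groups)
             for b in groups[i + 1:]],
            columns=["group1", "group2", "meandiff", "p_adj", "reject"])
    else:
        f_res = stats.f_oneway(*arrays)
        f_stat, p = float(f_res.statistic), float(f_res.pvalue)
        hsd = pairwise_tukeyhsd(
            endog=values[value_col].to_numpy(dtype=float),
            groups=values[group_col].to_numpy(), alpha=alpha)
        tukey_df = pd.DataFrame(
            hsd.summary().data[1:],
            columns=[c for c in hsd.summary().data[0]]).rename(
                columns={"p-adj": "p_adj"})[
                ["group1", "group2", "meandiff", "p_adj", "reject"]]
    significant = {frozenset((r.group1, r.group2))
                   for r in tukey_df.itertuples() if bool(r.reject)}
    letters = _compact_letters(groups, significant)
    return ExpressionTest(f_statistic=f_stat, p_value=p, tukey=tukey_df,
                          letters=letters)


def expression_report(expr: pd.DataFrame, test: ExpressionTest,
                      value_col: str = "rel_expr") -> str:
    """Plain-text summary: group means +/- SE, letters, omnibus test."""
    summary = expr.groupby("group")[value_col].agg(["mean", "sem", "count"])
    summary["letters"] = [test.letters.get(g, "") for g in summary.index]
    lines = [
        "Relative expression (2^-ddCt) by group:",
        summary.round(4).to_string(),
        "",
        f"One-way ANOVA: F = {test.f_statistic:.4g}, p = {test.p_value:.4g}",
        "",
        "Tukey HSD pairwise comparisons:",
        test.tukey.to_string(index=False),
    ]
    return "\n".join(lines)
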