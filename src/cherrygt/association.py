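"""Genotype-by-strain association: frequency tables and Pearson chi-square.

Counts genotype classes per colour strain at one locus, reports the
mutant (minor) allele frequency from pooled read counts, and tests
independence of strain and genotype with the plain Pearson chi-square
statistic (no continuity correction unless asked).  Unclassifiable calls
are non-calls and are excluded from tables by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssociationResult:
    statistic: float
    df: int
    p_value: float
    low_expected: bool  # any expected cell count < 5


def genotype_frequency_table(calls: pd.DataFrame, sheet, locus_id: str,
                             include_unclassifiable: bool = False
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Strain x genotype-class counts and within-strain proportions.

    ``calls`` is the long-format calling table; strains come from the
    sample sheet.  Returns (counts, proportions); proportions are over
    the included classes and sum to 1 per strain with any calls.
    """
    sub = calls[calls["locus_id"] == locus_id]
    if sub.empty:
        raise ValueError(f"no calls for locus {locus_id!r}")
    strain_of = sheet.strain_of() if hasattr(sheet, "strain_of") else dict(sheet)
    sub = sub.assign(strain=sub["individual_id"].map(strain_of))
    if sub["strain"].isna().any():
        missing = sub.loc[sub["strain"].isna(), "individual_id"].unique()
        raise ValueError(f"individuals absent from sample sheet: {list(missing)[:5]}")
    if not include_unclassifiable:
        sub = sub[sub["call"] != "unclassifiable"]
    table = pd.crosstab(sub["strain"], sub["call"])
    table = table.loc[:, [c for c in ("hom_ref", "het", "hom_alt", "unclassifiable")
                          if c in table.columns]]
    props = table.div(table.sum(axis=1), axis=0)
    return table, props


def mutant_allele_frequency(n_ref: int, n_alt: int) -> float:
    """Mutant (minor) allele frequency: alt reads over total ref+alt reads."""
    total = n_ref + n_alt
    if total <= 0:
        raise ValueError("mutant allele frequency undefined on zero ref+alt reads")
    return n_alt / total


def aggregate_mutant_allele_frequency(calls: pd.DataFrame, locus_id: str,
                                      strains: pd.Series | dict | None = None,
                                      strain: str | None = None) -> float:
    """Pooled mutant allele frequency for one locus, optionally one strain."""
    sub = calls[calls["locus_id"] == locus_id]
    if strain is not None:
        if strains is None:
            raise ValueError("strain filtering requires a strain mapping")
        mapping = strains.strain_of() if hasattr(strains, "strain_of") else dict(strains)
        sub = sub[sub["individual_id"].map(mapping) == strain]
    return mutant_allele_frequency(int(sub["n_ref"].sum()), int(sub["n_alt"].sum()))


def _clean_table(table: pd.DataFrame) -> pd.DataFrame:
    """Drop all-zero rows/columns; they carry no information for the test."""
    arr = table.to_numpy()
    if (arr < 0).any():
        raise ValueError("contingency table counts must be nonnegative")
    keep_rows = arr.sum(axis=1) > 0
    keep_cols = arr.sum(axis=0) > 0
    if not keep_rows.all() or not keep_cols.all():
        logger.info("dropping %d zero rows and %d zero columns before chi-square",
                    (~keep_rows).sum(), (~keep_cols).sum())
    return table.loc[keep_rows, keep_cols]


def pearson_chi_square(table: pd.DataFrame, yates: bool = False) -> AssociationResult:
    """Pearson chi-square test of independence on a strain x genotype table."""
    clean = _clean_table(table)
    if clean.shape[0] < 2 or clean.shape[1] < 2:
        raise ValueError(
            f"need at least a 2x2 table after dropping empty margins, got {clean.shape}")
    res = stats.chi2_contingency(clean.to_numpy(), correction=yates)
    return AssociationResult(
        statistic=float(res.statistic), df=int(res.dof), p_value=float(res.pvalue),
        low_expected=bool((res.expected_freq < 5).any()))


def pairwise_strain_tests(table: pd.DataFrame, focal_strain: str,
                          yates: bool = False) -> pd.DataFrame:
    """Chi-square of one strain against each other strain and against the rest.

    Builds 2 x k subtables (focal row vs one comparison row, plus focal
    vs all others pooled) and reports raw and Bonferroni-adjusted
    p-values over the per-strain comparisons.
    """
    if focal_strain not in table.index:
        raise ValueError(f"focal strain {focal_strain!r} not in table")
    others = [s for s in table.index if s != focal_strain]
    if not others:
        raise ValueError("need at least two strains")
    comparisons: list[tuple[str, pd.DataFrame]] = [
        (other, table.loc[[focal_strain, other]]) for other in others]
    pooled = pd.DataFrame(
        [table.loc[focal_strain], table.loc[others].sum()],
        index=[focal_strain, "pooled_others"])
    comparisons.append(("pooled_others", pooled))

    m = len(others) if len(others) > 1 else 1  # adjust over per-strain tests
    rows = []
    for name, sub in comparisons:
        res = pearson_chi_square(sub, yates=yates)
        adj = min(1.0, res.p_value * m) if name != "pooled_others" else res.p_value
        rows.append((focal_strain, name, res.statistic, res.df, res.p_value,
                     adj, res.low_expected))
    return pd.DataFrame(rows, columns=[
        "focal", "versus", "chi2", "df", "p_raw", "p_adjusted", "low_expected"])


def association_report(calls: pd.DataFrame, sheet, locus_id: str,
                       focal_strain: str = "yellow") -> str:
    """Plain-text per-locus association summary."""
    table, props = genotype_frequency_table(calls, sheet, locus_id)
    omnibus = pearson_chi_square(table)
    pairwise = pairwise_strain_tests(table, focal_strain)
    maf = aggregate_mutant_allele_frequency(calls, locus_id)
    lines = [
        f"Locus {locus_id}",
        "", "Genotype counts by strain:", table.to_string(),
        "", "Genotype proportions by strain:", props.round(3).to_string(),
        "", f"Pooled mutant allele frequency: {maf:.4f}",
        "", (f"Omnibus Pearson chi-square: X2 = {omnibus.statistic:.3f}, "
             f"df = {omnibus.df}, p = {omnibus.p_value:.3g}"
             + ("  [expected counts < 5]" if omnibus.low_expected else "")),
        "", f"Pairwise tests, focal strain {focal_strain}:",
        pairwise.to_string(index=False,
                           float_format=lambda x: f"{x:.4g}"),
    ]
    return "\n".join(lines)


def calls_to_truth_style(truth: pd.DataFrame) -> pd.DataFrame:
    """Adapt a truth-genotype table to the calling-table schema.

    Lets association run directly on simulated ground truth (the
    genotype-level view of the default scenario) without read simulation;
    counts are filled with zeros and every genotype becomes its own call.
    """
    out = truth.rename(columns={"genotype": "call"}).copy()
    for col in ("n_ref", "n_alt", "n_other", "depth"):
        out[col] = 0
    out["afi"] = np.nan
    return out[["individual_id", "locus_id", "n_ref", "n_alt", "n_other",
                "depth", "afi", "call"]]
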