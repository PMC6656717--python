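"""Case-control and case-reference allele/genotype frequency comparisons.

All comparisons funnel through one Pearson chi-squared code path (no
continuity correction by default, matching how such case-control tables are
conventionally reported; Yates correction is available for 2x2 tables).
Reference-panel comparisons are expressed as pseudo-counts at the stated
panel size so they share that code path.  No multiple-testing adjustment is
applied; reports annotate the Bonferroni threshold for context only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort_io import GenotypeMatrix, SnvAnnotation
from .errors import DegenerateDataError, ValidationError


@dataclass
class FreqComparison:
    """A chi-squared comparison of allele or genotype counts between groups."""

    rsid: str
    counts: np.ndarray  # the contingency table actually tested
    group_labels: list[str]
    statistic: float
    df: int
    p: float
    mode: str = "allele"


def allele_counts(gm: GenotypeMatrix, rsid: str, subset=None) -> tuple[int, int]:
    """Risk-allele count and total chromosomes over a subject subset.

    Missing genotypes are excluded from both numerator and denominator.
    """
    g = gm.column(rsid)
    if subset is not None:
        g = g[np.asarray(subset, dtype=bool)]
    g = g[~np.isnan(g)]
    if g.size == 0:
        raise DegenerateDataError(f"{rsid}: no non-missing genotypes in subset")
    return int(g.sum()), 2 * int(g.size)


def chi2_contingency(table) -> tuple[float, int, float]:
    """Pearson chi-squared test on a counts table, no continuity correction.

    Expected counts below 5 trigger a warning (not an error); a zero row or
    column margin makes the test undefined and raises.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValidationError("contingency table must be at least 2x2")
    if (t < 0).any():
        raise ValidationError("negative count in contingency table")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        raise DegenerateDataError("zero row or column margin; chi-squared undefined")
    stat, p, df, expected = stats.chi2_contingency(t, correction=False)
    if (expected < 5).any():
        warnings.warn(
            f"{int((expected < 5).sum())} expected cell count(s) below 5; "
            "chi-squared approximation may be poor",
            stacklevel=2,
        )
    return float(stat), int(df), float(p)


def chi2_contingency_yates(table) -> tuple[float, int, float]:
    """2x2 chi-squared with Yates continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValidationError("Yates correction applies to 2x2 tables only")
    stat, p, df, _ = stats.chi2_contingency(t, correction=True)
    return float(stat), int(df), float(p)


def compare_groups(
    gm: GenotypeMatrix,
    rsid: str,
    group_labels,
    mode: str = "allele",
) -> FreqComparison:
    """Compare allele (2xk) or genotype (3xk) counts across subject groups.

    ``group_labels`` assigns each subject to a group; groups appear in first-
    occurrence order as table columns.
    """
    labels = np.asarray(group_labels)
    if labels.shape[0] != gm.n_subjects:
        raise ValidationError("group labels length does not match subjects")
    groups = list(dict.fromkeys(labels.tolist()))
    if not 2 <= len(groups) <= 3:
        raise ValidationError("compare_groups expects two or three groups")
    g = gm.column(rsid)
    cols = []
    for grp in groups:
        gg = g[(labels == grp) & ~np.isnan(g)]
        if gg.size == 0:
            raise DegenerateDataError(f"{rsid}: group {grp!r} has no genotyped subjects")
        if mode == "allele":
            risk = gg.sum()
            cols.append([risk, 2 * gg.size - risk])
        elif mode == "genotype":
            cols.append([(gg == c).sum() for c in (2.0, 1.0, 0.0)])
        else:
            raise ValidationError(f"unknown mode {mode!r}")
    table = np.asarray(cols, dtype=float).T  # rows = categories, cols = groups
    stat, df, p = chi2_contingency(table)
    return FreqComparison(rsid, table, [str(x) for x in groups], stat, df, p, mode=mode)


def compare_to_reference(case_count: int, case_total: int, annotation: SnvAnnotation) -> FreqComparison:
    """Compare case risk-allele counts with a reference panel frequency.

    The reference is turned into pseudo-counts round(ref_freq * ref_n) over
    ref_n chromosomes so the comparison runs through the same 2x2 chi-squared
    path as the case-control tests.
    """
    if annotation.ref_n <= 0:
        raise ValidationError(
            f"{annotation.rsid}: reference panel size (ref_n) required for the reference comparison"
        )
    if case_count > case_total:
        raise ValidationError("case risk-allele count exceeds total chromosomes")
    ref_risk = round(annotation.ref_freq * annotation.ref_n)
    table = np.array(
        [
            [case_count, ref_risk],
            [case_total - case_count, annotation.ref_n - ref_risk],
        ],
        dtype=float,
    )
    stat, df, p = chi2_contingency(table)
    return FreqComparison(annotation.rsid, table, ["cases", "reference"], stat, df, p, mode="allele")


def hwe_chi2(gm: GenotypeMatrix, rsid: str) -> tuple[float, float]:
    """1-df chi-squared check of Hardy-Weinberg genotype proportions (QC)."""
    g = gm.column(rsid)
    g = g[~np.isnan(g)]
    n = g.size
    if n == 0:
        raise DegenerateDataError(f"{rsid}: no genotypes for HWE check")
    obs = np.array([(g == 2).sum(), (g == 1).sum(), (g == 0).sum()], dtype=float)
    p_hat = g.sum() / (2 * n)
    exp = n * np.array([p_hat**2, 2 * p_hat * (1 - p_hat), (1 - p_hat) ** 2])
    if (exp == 0).any():
        return 0.0, 1.0  # monomorphic: trivially consistent
    stat = float(((obs - exp) ** 2 / exp).sum())
    return stat, float(stats.chi2.sf(stat, df=1))
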