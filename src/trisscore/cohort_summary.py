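"""Descriptive cohort tables and association tests.

Covers the standard registry report: an age-group x cause frequency table
with row percentages and margins, score means/SDs stratified by outcome or
trauma type with a two-sample comparison, and Pearson chi-square tests of
association for contingency tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .registry_io import Registry

__all__ = [
    "DEFAULT_AGE_BINS", "FrequencyTable", "GroupSummary",
    "frequency_table", "group_means", "chi_square_association",
]

#: Decadal-ish age bins (inclusive bounds), 2-82 years.
DEFAULT_AGE_BINS = ((2, 12), (13, 22), (23, 32), (33, 42),
                    (43, 52), (53, 62), (63, 72), (73, 82))


def _bin_label(lo: int, hi: int) -> str:
    return f"{lo}-{hi}"


@dataclass(frozen=True, eq=False)
class FrequencyTable:
    """Counts and row percentages of a grouping variable by age group.

    ``counts`` has one row per age bin and one column per group level plus
    a ``Total`` row and column; ``row_percent`` gives each cell as a
    percentage of its row total (margins excluded).
    """

    counts: pd.DataFrame
    row_percent: pd.DataFrame

    @property
    def n(self) -> int:
        return int(self.counts.loc["Total", "Total"])


def frequency_table(data, age_bins=DEFAULT_AGE_BINS,
                    group_field: str = "cause") -> FrequencyTable:
    """Cross-tabulate age group against ``group_field`` with margins.

    ``data`` is a Registry or a registry DataFrame.  Every age must fall in
    one of the (inclusive) ``age_bins``; an out-of-range age raises an
    error naming the record.
    """
    df = data.to_frame() if isinstance(data, Registry) else data
    ages = df["age"].to_numpy()
    labels = [_bin_label(lo, hi) for lo, hi in age_bins]
    group = np.full(len(df), -1)
    for i, (lo, hi) in enumerate(age_bins):
        group[(ages >= lo) & (ages <= hi)] = i
    if np.any(group < 0):
        pos = int(np.flatnonzero(group < 0)[0])
        pid = df["patient_id"].iloc[pos]
        raise ValueError(
            f"age {ages[pos]} of record {pid!r} falls outside all age bins")
    age_cat = pd.Categorical.from_codes(group, categories=labels)
    counts = pd.crosstab(age_cat, df[group_field], dropna=False)
    counts = counts.reindex(index=labels, fill_value=0)
    counts.index.name = "age_group"
    row_pct = counts.div(counts.sum(axis=1).replace(0, np.nan), axis=0) * 100
    counts.loc["Total"] = counts.sum(axis=0)
    counts["Total"] = counts.sum(axis=1)
    return FrequencyTable(counts=counts, row_percent=row_pct)


@dataclass(frozen=True, eq=False)
class GroupSummary:
    """Per-stratum mean, sample SD and n of a score, plus a comparison p.

    ``p_value`` is from Welch's unequal-variance two-sample t-test and is
    only defined when the stratifier has exactly two levels.
    """

    score_field: str
    stratifier: str
    stats: pd.DataFrame  # index: stratum; columns: n, mean, sd
    p_value: float | None


def group_means(data, score_field: str, stratifier: str) -> GroupSummary:
    """Mean +/- SD of ``score_field`` per level of ``stratifier``.

    Requires at least two records per stratum (for the sample SD).  With
    exactly two strata a two-sided Welch t-test p-value is attached.
    """
    df = data.to_frame() if isinstance(data, Registry) else data
    groups = df.groupby(stratifier, observed=True)[score_field]
    sizes = groups.size()
    if len(sizes) == 0:
        raise ValueError(f"no strata found for {stratifier!r}")
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise ValueError(
            f"stratum {small!r} of {stratifier!r} has fewer than 2 records")
    table = pd.DataFrame({
        "n": sizes,
        "mean": groups.mean(),
        "sd": groups.std(ddof=1),
    })
    p_value = None
    if len(sizes) == 2:
        a, b = (g.to_numpy(dtype=float) for _, g in groups)
        if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
            p_value = 1.0  # identical degenerate groups; t-test is 0/0
        else:
            p_value = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return GroupSummary(score_field=score_field, stratifier=stratifier,
                        stats=table, p_value=p_value)


def chi_square_association(table) -> tuple[float, float]:
    """Pearson chi-square test (no continuity correction) on a count table.

    ``table`` is a 2D array-like of non-negative counts with at least two
    non-empty rows and columns.  Returns (statistic, p_value).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or np.any(t < 0):
        raise ValueError("table must be a 2D array of non-negative counts")
    if np.count_nonzero(t.sum(axis=1)) < 2 or np.count_nonzero(t.sum(axis=0)) < 2:
        raise ValueError("degenerate table: need two non-empty rows and columns")
    res = stats.chi2_contingency(t, correction=False)
    return float(res.statistic), float(res.pvalue)
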