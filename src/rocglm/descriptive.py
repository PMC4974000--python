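"""Group-comparison layer: per-group summaries, Student t, Fisher exact,
Pearson correlation, and the assembled characteristics table."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, GROUPS

__all__ = [
    "GroupSummary",
    "student_t",
    "student_t_from_stats",
    "fisher_exact_2x2",
    "pearson_r",
    "table1",
    "STUDY_TABLE1_VARIABLES",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupSummary:
    """One characteristics-table row: per-group summary plus the group test."""

    variable: str
    kind: str                 # "continuous" | "categorical"
    n_a: int
    n_b: int
    summary_a: str            # "mean (SD)" or "count (%)"
    summary_b: str
    test: str                 # "Student t" | "Fisher exact"
    p_value: float


def student_t(group_a, group_b) -> tuple[float, float]:
    """Classical pooled-variance two-sample Student t test.

    Returns (t, two-sided p) with df = n_a + n_b - 2.  Welch's correction is
    deliberately not applied: the test is the textbook Student form.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    res = stats.ttest_ind(a, b, equal_var=True)
    if not math.isfinite(res.statistic):
        raise ValueError("zero pooled variance: t statistic undefined")
    return float(res.statistic), float(res.pvalue)


def student_t_from_stats(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
) -> tuple[float, float]:
    """Pooled Student t from per-group (mean, SD, n) summaries.

    Lets published table rows be checked without the raw data; agrees with
    :func:`student_t` on raw samples to machine precision.
    """
    res = stats.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=True
    )
    if not math.isfinite(res.statistic):
        raise ValueError("zero pooled variance: t statistic undefined")
    return float(res.statistic), float(res.pvalue)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Two-sided by the minimum-likelihood convention: sum of probabilities of
    all tables (with the observed margins) no more probable than the
    observed one.  A zero margin makes every alternative table impossible;
    p = 1 by convention (logged).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("counts must be non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        log.info("Fisher exact on a table with a zero margin: p = 1 by convention")
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise ValueError("need paired samples of size >= 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("correlation undefined for a constant input")
    return float(stats.pearsonr(xa, ya)[0])


#: Default variable layout of the characteristics table: (cohort column,
#: display label, kind).  ``sex`` is the one categorical entry.
STUDY_TABLE1_VARIABLES: tuple[tuple[str, str, str], ...] = (
    ("age", "Age, yrs", "continuous"),
    ("sex", "No. of females (%)", "categorical"),
    ("bcva_logmar", "Visual acuity, logMAR", "continuous"),
    ("iop", "Intraocular pressure, mmHg", "continuous"),
    ("spherical_equivalent", "Spherical equivalent, diopters", "continuous"),
    ("axial_length", "Axial length, mm", "continuous"),
    ("md", "Mean deviation, decibels", "continuous"),
    ("psd", "Pattern standard deviation, decibels", "continuous"),
    ("vfi", "Visual field index, %", "continuous"),
    ("disc_area_measured", "Optic disc area, mm^2", "continuous"),
    ("disc_area_corrected", "Corrected optic disc area, mm^2", "continuous"),
    ("rnfl_avg", "Average RNFL thickness, um", "continuous"),
    ("gcipl_avg", "Average GCIPL thickness, um", "continuous"),
    ("gcipl_min", "Minimum GCIPL thickness, um", "continuous"),
)


def table1(
    cohort: Cohort,
    variables: Sequence[tuple[str, str, str]] = STUDY_TABLE1_VARIABLES,
) -> list[GroupSummary]:
    """Characteristics table: per-group mean (SD) with a pooled Student t per
    continuous variable, count (%) with a Fisher exact test per categorical.

    Group A is glaucoma, group B control.  Unknown variable names raise a
    configuration error.
    """
    cohort.require_both_groups()
    frame = cohort.frame
    ga = frame[frame["group"] == GROUPS[0]]
    gb = frame[frame["group"] == GROUPS[1]]
    rows: list[GroupSummary] = []
    for col, label, kind in variables:
        if col not in frame.columns:
            raise KeyError(f"unknown cohort variable: {col!r}")
        if kind == "continuous":
            a = ga[col].dropna().to_numpy(dtype=float)
            b = gb[col].dropna().to_numpy(dtype=float)
            _, p = student_t(a, b)
            rows.append(
                GroupSummary(
                    variable=label,
                    kind=kind,
                    n_a=a.size,
                    n_b=b.size,
                    summary_a=f"{a.mean():.2f} ({a.std(ddof=1):.2f})",
                    summary_b=f"{b.mean():.2f} ({b.std(ddof=1):.2f})",
                    test="Student t",
                    p_value=p,
                )
            )
        elif kind == "categorical":
            # 2x2: level-of-interest (first level alphabetically, e.g.
            # "female") vs rest, by group
            levels = sorted(set(frame[col]) - {""})
            if not levels:
                raise ValueError(f"categorical variable {col!r} has no data")
            lvl = levels[0]
            tab = np.array(
                [
                    [int((ga[col] == lvl).sum()), int((ga[col] != lvl).sum())],
                    [int((gb[col] == lvl).sum()), int((gb[col] != lvl).sum())],
                ]
            )
            p = fisher_exact_2x2(tab)
            rows.append(
                GroupSummary(
                    variable=label,
                    kind=kind,
                    n_a=len(ga),
                    n_b=len(gb),
                    summary_a=f"{tab[0, 0]} ({100 * tab[0, 0] / max(len(ga), 1):.1f})",
                    summary_b=f"{tab[1, 0]} ({100 * tab[1, 0] / max(len(gb), 1):.1f})",
                    test="Fisher exact",
                    p_value=p,
                )
            )
        else:
            raise ValueError(f"unknown variable kind: {kind!r}")
    return rows


def table1_frame(cohort: Cohort, variables=STUDY_TABLE1_VARIABLES) -> pd.DataFrame:
    """:func:`table1` as a serializable DataFrame."""
    return pd.DataFrame([s.__dict__ for s in table1(cohort, variables)])
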