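"""Baseline ("Table 1" style) group comparisons from printed summaries.

Two-group comparisons reconstructed from summary statistics alone: a
Yates-continuity-corrected chi-square on 2x2 counts and a Welch t statistic
(unequal variances, Welch-Satterthwaite degrees of freedom) from group
means, SDs and sizes. p-values come from the chi-square(1) and t(df)
reference distributions but are reporting extras, not the comparison itself.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import CohortTable, ValidationError


@dataclass(frozen=True)
class FourfoldTable:
    """2x2 counts: group 1 a successes / b failures, group 2 c / d."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("cell counts must be non-negative")
        if self.a + self.b + self.c + self.d < 1:
            raise ValidationError("table must contain at least one observation")


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError("sd must be non-negative")
        if self.n < 2:
            raise ValidationError("n must be >= 2")


def chi_square_corrected(table: FourfoldTable) -> float:
    """Yates-corrected chi-square statistic for a 2x2 table.

    ``n * (max(0, |ad - bc| - n/2))**2 / (r1 * r2 * c1 * c2)``, with the
    correction floored at 0 so a near-proportional table gives 0 rather
    than a negative statistic.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValidationError("chi-square undefined: a margin total is zero")
    num = max(0.0, abs(a * d - b * c) - n / 2.0)
    return float(n * num**2 / (r1 * r2 * c1 * c2))


def chi_square_uncorrected(table: FourfoldTable) -> float:
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValidationError("chi-square undefined: a margin total is zero")
    return float(n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2))


def welch_t(group1: GroupSummary, group2: GroupSummary) -> tuple[float, float]:
    """Welch t statistic and Welch-Satterthwaite df from group summaries.

    Sign convention: ``t = (mean2 - mean1) / se``, so a higher first-group
    mean gives a negative t.
    """
    v1 = group1.sd**2 / group1.n
    v2 = group2.sd**2 / group2.n
    if v1 + v2 == 0:
        raise ValidationError("Welch t undefined: both groups have zero variance")
    t = (group2.mean - group1.mean) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (group1.n - 1) + v2**2 / (group2.n - 1))
    return float(t), float(df)


def welch_p(t: float, df: float) -> float:
    return float(2 * stats.t.sf(abs(t), df))


def chi_square_p(statistic: float) -> float:
    return float(stats.chi2.sf(statistic, df=1))


def remission_percent(outcome: np.ndarray) -> float:
    """Percentage remitted, rounded to one decimal (100/161 -> 62.1)."""
    outcome = np.asarray(outcome)
    if outcome.size == 0:
        raise ValidationError("empty outcome vector")
    return round(100.0 * float(outcome.mean()), 1)


def cohort_table1(cohort: CohortTable) -> "pd.DataFrame":
    """Remitter vs non-remitter comparison rows computed from a cohort.

    Rows: remission count/percent, per-item Welch comparisons of baseline
    scores, the baseline total score, and (when a moderator is present) a
    corrected chi-square of study membership by remission.
    """
    import pandas as pd

    rem = cohort.outcome == 1
    rows = []
    rows.append(
        {
            "variable": "remitted",
            "remitters": int(rem.sum()),
            "non_remitters": int((~rem).sum()),
            "statistic": np.nan,
            "df": np.nan,
            "p": np.nan,
            "test": f"{remission_percent(cohort.outcome)}% remitted",
        }
    )
    totals = cohort.scores.sum(axis=1)
    for label, values in [("baseline_total", totals)] + [
        (lbl, cohort.scores[:, j]) for j, lbl in enumerate(cohort.scale.labels)
    ]:
        g1 = GroupSummary(float(values[rem].mean()), float(values[rem].std(ddof=1)), int(rem.sum()))
        g2 = GroupSummary(
            float(values[~rem].mean()), float(values[~rem].std(ddof=1)), int((~rem).sum())
        )
        t, df = welch_t(g1, g2)
        rows.append(
            {
                "variable": label,
                "remitters": g1.mean,
                "non_remitters": g2.mean,
                "statistic": t,
                "df": df,
                "p": welch_p(t, df),
                "test": "welch_t",
            }
        )
    if cohort.moderator is not None:
        m = cohort.moderator == 1
        tab = FourfoldTable(
            int((rem & m).sum()), int((rem & ~m).sum()), int((~rem & m).sum()), int((~rem & ~m).sum())
        )
        chi = chi_square_corrected(tab)
        rows.append(
            {
                "variable": "study_by_remission",
                "remitters": int((rem & m).sum()),
                "non_remitters": int((~rem & m).sum()),
                "statistic": chi,
                "df": 1.0,
                "p": chi_square_p(chi),
                "test": "chi_square_corrected",
            }
        )
    return pd.DataFrame(rows)
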