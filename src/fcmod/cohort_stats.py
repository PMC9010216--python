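"""Group-comparison statistics for cohort characteristics tables.

Two-sample t-tests computable from raw data or from printed (n, mean, SD)
summaries, Pearson chi-square tests for categorical variables, and the PSQI
poor-sleeper rule (global score >= 5).  Welch (unequal-variance) is the
default continuous test; the pooled-variance Student variant is always
available and reports name which was used, because published tables do not
always state the variant.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "TestResult",
    "welch_t",
    "student_t",
    "chi_square",
    "poor_sleeper_flag",
    "group_table",
    "summarize",
]

POOR_SLEEPER_CUTOFF = 5


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float
    test: str
    flagged_degenerate: bool = False


def summarize(values) -> GroupSummary:
    """(n, mean, sample SD) of a raw data vector."""
    v = np.asarray(values, dtype=float)
    return GroupSummary(n=v.size, mean=float(v.mean()), sd=float(v.std(ddof=1)))


def _degenerate(a: GroupSummary, b: GroupSummary):
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            return TestResult(0.0, float(a.n + b.n - 2), 1.0, "degenerate", True)
        return TestResult(float(np.inf) * np.sign(a.mean - b.mean),
                          float(a.n + b.n - 2), 0.0, "degenerate", True)
    return None


def welch_t(a: GroupSummary, b: GroupSummary) -> TestResult:
    """Unequal-variance two-sample t-test with Welch–Satterthwaite df."""
    deg = _degenerate(a, b)
    if deg:
        return deg
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    t = (a.mean - b.mean) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(p), "welch")


def student_t(a: GroupSummary, b: GroupSummary) -> TestResult:
    """Pooled-variance two-sample t-test, df = n_a + n_b − 2."""
    deg = _degenerate(a, b)
    if deg:
        return deg
    df = a.n + b.n - 2
    s2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    t = (a.mean - b.mean) / np.sqrt(s2 * (1 / a.n + 1 / b.n))
    p = 2 * stats.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(p), "student")


def chi_square(counts, continuity: bool = False) -> TestResult:
    """Pearson chi-square test of independence on an r×c contingency table.

    No continuity correction by default; ``continuity=True`` applies Yates'
    correction (2×2 tables only, as in scipy).
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or np.any(table < 0):
        raise ValueError("contingency table must be 2-D with nonnegative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero marginal")
    res = stats.chi2_contingency(table, correction=continuity)
    return TestResult(float(res.statistic), float(res.dof), float(res.pvalue),
                      "chi2_yates" if continuity else "chi2")


def poor_sleeper_flag(psqi_total: float) -> bool:
    """True iff the global PSQI score is >= 5 (the poor-sleeper cutoff)."""
    if not 0 <= psqi_total <= 21:
        raise ValueError(f"PSQI total {psqi_total} outside [0, 21]")
    return psqi_total >= POOR_SLEEPER_CUTOFF


def group_table(
    cohort: pd.DataFrame,
    continuous: tuple[str, ...] = ("age", "psqi"),
    categorical: tuple[str, ...] = ("sex",),
    test: str = "welch",
    flag_threshold: float = 0.05,
) -> pd.DataFrame:
    """Characteristics-table comparison of the pain (group=1) vs no-pain groups.

    One row per variable: group summaries, the test used, statistic, df, p,
    and a significance flag at *flag_threshold* (set it to a Bonferroni level
    to mirror corrected flagging).
    """
    if "group" not in cohort.columns:
        raise ValueError("cohort table must contain a 'group' column")
    g1 = cohort[cohort["group"] == 1]
    g0 = cohort[cohort["group"] == 0]
    if len(g1) < 2 or len(g0) < 2:
        raise ValueError("each group needs at least 2 subjects")
    t_fun = {"welch": welch_t, "student": student_t}[test]
    rows = []
    for var in continuous:
        a, b = summarize(g1[var]), summarize(g0[var])
        r = t_fun(a, b)
        rows.append({
            "variable": var,
            "pain_summary": f"{a.mean:.2f} ± {a.sd:.2f} (n={a.n})",
            "nopain_summary": f"{b.mean:.2f} ± {b.sd:.2f} (n={b.n})",
            "test": r.test, "statistic": r.statistic, "df": r.df, "p": r.p,
            "flagged": r.p < flag_threshold,
        })
    for var in categorical:
        levels = sorted(cohort[var].unique())
        table = np.array([
            [(g[var] == lev).sum() for lev in levels] for g in (g1, g0)
        ])
        r = chi_square(table)
        rows.append({
            "variable": var,
            "pain_summary": "/".join(str(c) for c in table[0]),
            "nopain_summary": "/".join(str(c) for c in table[1]),
            "test": r.test, "statistic": r.statistic, "df": r.df, "p": r.p,
            "flagged": r.p < flag_threshold,
        })
    return pd.DataFrame(rows)
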