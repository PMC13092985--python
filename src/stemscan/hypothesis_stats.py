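"""Hypothesis tests and the pairwise-identity machinery used by the survey.

The two-sample proportion Z-test, Welch and pooled-variance Student t, one-way
ANOVA F and Cohen's d are computed from their textbook formulas with tail
probabilities taken from scipy's distributions; the Shapiro-Wilk gate and the
tie-corrected normal-approximation Mann-Whitney U come from scipy.stats.  The
global aligner is a linear-gap Needleman-Wunsch whose identity denominator
includes gapped columns (terminal gaps included); cohort *comparisons*, not
absolute identity values, are the supported output, since identity is
convention-dependent.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "AlignmentResult",
    "proportion_z_test",
    "gated_compare",
    "student_t",
    "welch_t",
    "mann_whitney_u",
    "t_two_sided_p",
    "f_upper_p",
    "one_way_anova",
    "cohens_d",
    "nw_align",
    "identity_cohorts",
    "test_result_row",
]


@dataclass
class TestResult:
    statistic: float
    df: object  # float, (float, float) pair, or None
    p_value: float
    effect_size: Optional[float]
    method: str
    n_per_group: tuple = ()


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: int
    identity_pct: float


# ---------------------------------------------------------------------------
# Closed-form helpers
# ---------------------------------------------------------------------------


def t_two_sided_p(t: float, df: float) -> float:
    """Two-sided Student-t tail probability; supports non-integer df."""
    if df <= 0:
        raise ValueError("df must be positive")
    return float(2.0 * sps.t.sf(abs(t), df))


def f_upper_p(F: float, df1: int, df2: int) -> float:
    """Upper-tail F probability."""
    return float(sps.f.sf(F, df1, df2))


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------


def proportion_z_test(k1: int, n1: int, k2: int, n2: int) -> TestResult:
    """Two-sample proportion Z-test with a pooled proportion, two-sided."""
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2) or n1 < 1 or n2 < 1:
        raise ValueError("need 0 <= k <= n with n >= 1 in both groups")
    p_pool = (k1 + k2) / (n1 + n2)
    if p_pool in (0.0, 1.0):
        raise ValueError("degenerate pooled proportion (all successes or failures)")
    se = math.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    z = (k1 / n1 - k2 / n2) / se
    p = float(2.0 * sps.norm.sf(abs(z)))
    return TestResult(z, None, p, k1 / n1 - k2 / n2, "proportion_z", (n1, n2))


def student_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Independent two-sample Student t (pooled variance)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("need n >= 2 per group")
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return TestResult(float(t), float(df), t_two_sided_p(t, df),
                      cohens_d(a, b), "student_t", (na, nb))


def welch_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Welch's t with the Welch-Satterthwaite degrees of freedom."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("need n >= 2 per group")
    va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
    if va + vb == 0:
        raise ValueError("zero variance in both groups")
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    return TestResult(float(t), float(df), t_two_sided_p(t, df), None,
                      "welch_t", (na, nb))


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Mann-Whitney U, normal approximation with continuity and tie corrections."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if np.ptp(np.concatenate([a, b])) == 0:
        # every observation tied: no evidence either way
        return TestResult(len(a) * len(b) / 2.0, None, 1.0, None,
                          "mann_whitney_u", (len(a), len(b)))
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                           use_continuity=True)
    return TestResult(float(res.statistic), None, float(res.pvalue), None,
                      "mann_whitney_u", (len(a), len(b)))


def gated_compare(
    a: Sequence[float], b: Sequence[float], alpha: float = 0.05
) -> TestResult:
    """Normality-gated two-group comparison.

    Shapiro-Wilk is applied to each group at ``alpha``; a non-normal verdict in
    either sends the comparison down the Mann-Whitney U branch, otherwise the
    pooled-variance Student t is used.  The method label records which branch
    ran.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3 per group")
    normal = True
    for g in (a, b):
        if np.ptp(g) == 0:
            normal = False  # constant sample: trivially non-normal, use ranks
            continue
        if sps.shapiro(g).pvalue < alpha:
            normal = False
    return student_t(a, b) if normal else mann_whitney_u(a, b)


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way fixed-effects ANOVA; F with df (k-1, N-k)."""
    gs = [np.asarray(g, float) for g in groups]
    if len(gs) < 2 or any(len(g) < 2 for g in gs):
        raise ValueError("need >= 2 groups with n >= 2 each")
    N = sum(len(g) for g in gs)
    k = len(gs)
    grand = np.concatenate(gs).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df1, df2 = k - 1, N - k
    if ss_within == 0:
        raise ValueError("zero within-group variance")
    F = (ss_between / df1) / (ss_within / df2)
    return TestResult(float(F), (df1, df2), f_upper_p(F, df1, df2), None,
                      "one_way_anova", tuple(len(g) for g in gs))


def cohens_d(a: Sequence[float], b: Sequence[float]) -> float:
    """Cohen's d with the pooled standard deviation."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    return float((a.mean() - b.mean()) / math.sqrt(sp2))


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


def nw_align(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
    free_end_gaps: bool = False,
) -> AlignmentResult:
    """Optimal global (Needleman-Wunsch) alignment under a linear gap penalty.

    With ``free_end_gaps`` the alignment is semi-global (terminal gaps cost
    nothing), the appropriate mode when one sequence genuinely overhangs the
    other.  Ties are broken deterministically: diagonal over gap-in-b over
    gap-in-a.  ``identity_pct`` counts matching columns over the full
    alignment length, gapped (including terminal-gap) columns included.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    n, m = len(a), len(b)
    edge = 0 if free_end_gaps else gap
    score: list[list[int]] = [[edge * j for j in range(m + 1)]]
    for i in range(1, n + 1):
        prev = score[i - 1]
        row = [edge * i]
        ai = a[i - 1]
        for j in range(1, m + 1):
            best = prev[j - 1] + (match if ai == b[j - 1] else mismatch)
            up = prev[j] + gap
            if up > best:
                best = up
            left = row[j - 1] + gap
            if left > best:
                best = left
            row.append(best)
        score.append(row)

    # choose the end cell: (n, m) for global; best last-row/column cell for
    # semi-global, preferring (n, m) then later columns/rows on ties
    bi, bj = n, m
    if free_end_gaps:
        best_val = score[n][m]
        for j in range(m, -1, -1):
            if score[n][j] > best_val:
                best_val, bi, bj = score[n][j], n, j
        for i in range(n, -1, -1):
            if score[i][m] > best_val:
                best_val, bi, bj = score[i][m], i, m

    out_a: list[str] = ["-"] * (m - bj) + list(a[bi:])[::-1]
    out_b: list[str] = list(b[bj:])[::-1] + ["-"] * (n - bi)
    i, j = bi, bj
    while i > 0 and j > 0:
        if score[i][j] == score[i - 1][j - 1] + (
            match if a[i - 1] == b[j - 1] else mismatch
        ):
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif score[i][j] == score[i - 1][j] + gap:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    # leading free gaps (or penalized edge moves in global mode)
    out_a.extend(a[:i][::-1])
    out_b.extend("-" * i)
    out_a.extend("-" * j)
    out_b.extend(b[:j][::-1])
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    matches = sum(x == y and x != "-" for x, y in zip(aligned_a, aligned_b))
    identity = 100.0 * matches / len(aligned_a)
    return AlignmentResult(aligned_a, aligned_b, int(score[bi][bj]), identity)


def identity_cohorts(
    set4: Sequence[str], set5: Sequence[str], **align_kwargs
) -> dict:
    """Within-cohort pairwise identity distributions and their comparison.

    Returns medians of the two identity distributions, the Student t comparison
    and Cohen's d; raises on cohorts with fewer than two sequences or zero
    identity variance.
    """
    if len(set4) < 2 or len(set5) < 2:
        raise ValueError("each cohort needs >= 2 sequences")

    def pairwise(seqs: Sequence[str]) -> list[float]:
        return [
            nw_align(x, y, **align_kwargs).identity_pct
            for x, y in itertools.combinations(seqs, 2)
        ]

    id4, id5 = pairwise(set4), pairwise(set5)
    t = student_t(id4, id5)
    return {
        "median4": float(np.median(id4)),
        "median5": float(np.median(id5)),
        "identities4": id4,
        "identities5": id5,
        "t_test": t,
        "d": cohens_d(id4, id5),
    }


def test_result_row(result: TestResult) -> dict:
    """Uniform TSV row for any test result."""
    df = result.df
    if isinstance(df, tuple):
        df = ",".join(f"{x:g}" for x in df)
    elif df is not None:
        df = f"{df:g}"
    return {
        "method": result.method,
        "statistic": round(result.statistic, 6),
        "df": df if df is not None else "",
        "p_value": result.p_value,
        "effect_size": "" if result.effect_size is None else round(result.effect_size, 6),
        "n_per_group": ",".join(str(n) for n in result.n_per_group),
    }
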