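"""Hypothesis tests, their closed forms, and the global aligner."""

import itertools
import math
from functools import lru_cache

import numpy as np
import pytest
from scipy import stats as sps

from stemscan.hypothesis_stats import (
    cohens_d,
    f_upper_p,
    gated_compare,
    identity_cohorts,
    mann_whitney_u,
    nw_align,
    one_way_anova,
    proportion_z_test,
    student_t,
    t_two_sided_p,
    welch_t,
)

rng = np.random.default_rng(2024)


# ---------------------------------------------------------------------------
# distribution helpers
# ---------------------------------------------------------------------------


def test_welch_p_reproduces_reported_readthrough_comparisons():
    # reporter-assay quantification: Welch t against the negative control and
    # against the wild-type 5-bp variant
    assert t_two_sided_p(6.76, 2.86) == pytest.approx(0.0077, abs=5e-4)
    assert t_two_sided_p(6.57, 2.97) == pytest.approx(0.0074, abs=5e-4)


def test_anova_f_p_reproduces_reported_overall_effect():
    assert f_upper_p(24.72, 2, 6) == pytest.approx(0.0013, abs=5e-5)


def test_t_tail_converges_to_normal_at_large_df():
    for t in (0.5, 1.0, 1.96, 3.0):
        assert t_two_sided_p(t, 1e6) == pytest.approx(
            2 * sps.norm.sf(t), abs=1e-6
        )


def test_f_upper_p_df1_2_closed_form():
    for F in (0.3, 1.0, 4.7, 24.72):
        for d2 in (3, 6, 11):
            closed = (1 + 2 * F / d2) ** (-d2 / 2)
            assert f_upper_p(F, 2, d2) == pytest.approx(closed, abs=1e-10)


# ---------------------------------------------------------------------------
# proportion Z
# ---------------------------------------------------------------------------


def test_proportion_z_identical_groups():
    res = proportion_z_test(50, 100, 50, 100)
    assert res.statistic == 0 and res.p_value == 1


def test_proportion_z_against_normal_tail_oracle():
    res = proportion_z_test(60, 100, 40, 100)
    p_pool = 0.5
    se = math.sqrt(p_pool * 0.5 * (2 / 100))
    z = 0.2 / se
    assert res.statistic == pytest.approx(z)
    assert res.p_value == pytest.approx(math.erfc(z / math.sqrt(2)), rel=1e-12)


def test_proportion_z_antisymmetric_under_group_swap():
    a = proportion_z_test(37, 90, 61, 120)
    b = proportion_z_test(61, 120, 37, 90)
    assert a.statistic == pytest.approx(-b.statistic)
    assert a.p_value == pytest.approx(b.p_value)


def test_proportion_z_degenerate_pool_errors():
    with pytest.raises(ValueError):
        proportion_z_test(0, 10, 0, 10)
    with pytest.raises(ValueError):
        proportion_z_test(10, 10, 10, 10)


# ---------------------------------------------------------------------------
# t family, ANOVA, effect size (cross-checked against scipy)
# ---------------------------------------------------------------------------


def test_welch_student_anova_agree_with_scipy():
    for _ in range(20):
        a = rng.normal(0, 1, int(rng.integers(5, 30)))
        b = rng.normal(0.3, 2, int(rng.integers(5, 30)))
        w = welch_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert w.statistic == pytest.approx(ref.statistic)
        assert w.p_value == pytest.approx(ref.pvalue)

        s = student_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert s.statistic == pytest.approx(ref.statistic)
        assert s.p_value == pytest.approx(ref.pvalue)

        c = rng.normal(1, 1, 8)
        an = one_way_anova([a, b, c])
        ref = sps.f_oneway(a, b, c)
        assert an.statistic == pytest.approx(ref.statistic)
        assert an.p_value == pytest.approx(ref.pvalue)


def test_two_sided_p_invariant_under_group_swap():
    a = rng.normal(0, 1, 12)
    b = rng.normal(0.5, 1.5, 15)
    assert welch_t(a, b).p_value == pytest.approx(welch_t(b, a).p_value)
    assert student_t(a, b).p_value == pytest.approx(student_t(b, a).p_value)
    assert mann_whitney_u(a, b).p_value == pytest.approx(
        mann_whitney_u(b, a).p_value
    )


def test_cohens_d_zero_for_identical_groups_and_errors_on_constant():
    assert cohens_d([1, 2, 3], [1, 2, 3]) == 0
    with pytest.raises(ValueError):
        cohens_d([2, 2, 2], [2, 2, 2])


# ---------------------------------------------------------------------------
# gated comparison
# ---------------------------------------------------------------------------


def test_gated_compare_selects_rank_branch_for_lognormal():
    r = np.random.default_rng(7)
    picked = sum(
        gated_compare(r.lognormal(0, 1, 30), r.normal(5, 1, 30)).method
        == "mann_whitney_u"
        for _ in range(100)
    )
    assert picked >= 95


def test_gated_compare_selects_t_branch_for_normal_and_is_calibrated():
    r = np.random.default_rng(8)
    t_branch = 0
    for _ in range(100)[:]:
        res = gated_compare(r.normal(0, 1, 20), r.normal(0, 1, 20))
        t_branch += res.method == "student_t"
    assert t_branch >= 80  # Shapiro false-positive rate ~5% per group


def test_gated_compare_identical_groups_p_one():
    res = gated_compare([3.0, 3.0, 3.0, 3.0], [3.0, 3.0, 3.0, 3.0])
    assert res.p_value == 1.0


def test_gated_compare_rejects_tiny_groups():
    with pytest.raises(ValueError):
        gated_compare([1.0, 2.0], [1.0, 2.0, 3.0])


def test_mann_whitney_exact_enumeration_oracle_small_n():
    r = np.random.default_rng(9)
    for _ in range(10):
        a = r.normal(0, 1, 6)
        b = r.normal(0.8, 1, 7)
        ours = mann_whitney_u(a, b)
        exact = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        # the tie/continuity-corrected normal approximation tracks exact p
        assert ours.p_value == pytest.approx(exact.pvalue, abs=0.03)


# ---------------------------------------------------------------------------
# aligner
# ---------------------------------------------------------------------------


def brute_force_score(a, b, match=1, mismatch=-1, gap=-2):
    """Exhaustive recursive optimum over all global alignments."""

    @lru_cache(maxsize=None)
    def f(i, j):
        if i == len(a):
            return gap * (len(b) - j)
        if j == len(b):
            return gap * (len(a) - i)
        return max(
            f(i + 1, j + 1) + (match if a[i] == b[j] else mismatch),
            f(i + 1, j) + gap,
            f(i, j + 1) + gap,
        )

    return f(0, 0)


def test_nw_align_hand_examples():
    same = nw_align("ACGU", "ACGU")
    assert same.identity_pct == 100.0 and same.score == 4
    res = nw_align("ACGU", "ACGA")
    assert res.identity_pct == 75.0


def test_nw_align_matches_bruteforce_and_biopython():
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2

    r = np.random.default_rng(10)
    bases = np.array(list("ACGU"))
    for _ in range(60):
        a = "".join(r.choice(bases, size=r.integers(1, 9)))
        b = "".join(r.choice(bases, size=r.integers(1, 9)))
        res = nw_align(a, b)
        assert res.score == brute_force_score(a, b)
        assert res.score == aligner.score(a, b)
        assert res.aligned_a.replace("-", "") == a
        assert res.aligned_b.replace("-", "") == b
        assert len(res.aligned_a) == len(res.aligned_b)


def test_identity_cohorts_properties():
    seqs = ["ACGUACGUACGUACGU", "ACGUACGAACGUACGU", "ACGUACGUACGAACGU"]
    res = identity_cohorts(seqs, seqs)
    assert res["t_test"].statistic == pytest.approx(0.0)
    assert res["d"] == 0.0

    with pytest.raises(ValueError):
        identity_cohorts(["AC"], seqs)
    # identical sequences: medians 100 but zero variance -> error
    with pytest.raises(ValueError):
        identity_cohorts(["ACGU", "ACGU"], ["ACGU", "ACGU"])


def test_identity_decreases_with_mutation_rate():
    r = np.random.default_rng(11)
    bases = np.array(list("ACGU"))
    ancestor = r.choice(bases, size=60)
    medians = []
    for rate in (0.02, 0.10, 0.30):
        cohort = []
        for _ in range(5):
            s = ancestor.copy()
            hits = np.nonzero(r.random(60) < rate)[0]
            for h in hits:
                s[h] = r.choice(bases)
            cohort.append("".join(s))
        res = identity_cohorts(cohort, cohort)
        medians.append(res["median4"])
    assert medians[0] > medians[1] > medians[2]
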