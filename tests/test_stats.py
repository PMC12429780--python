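"""Exact-test kernel against independent oracles, and allele counting."""

import math
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from dqrisk import (
    Cohort,
    ContingencyTable2x2,
    count_haplotype_alleles,
    count_risk_alleles,
    fisher_exact_two_sided,
    freeman_halton_exact,
    hypergeometric_pmf,
    pairwise_group_tests,
    summarize_allele_counts,
    table1_fixture,
)
from dqrisk.cohort import Group, Individual, PLA2R1Genotype, normalize_allele_name
from dqrisk.cohort import DQHaplotype


def rational_fisher(a, b, c, d):
    """Exact-rational minimum-likelihood two-sided oracle."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(k):
        return Fraction(comb(r1, k) * comb(r2, c1 - k), denom)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return float(sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs))


def rational_freeman_halton(rows):
    """Exact-rational oracle for the R x 2 omnibus by full enumeration."""
    row_tot = [a + b for a, b in rows]
    c1 = sum(a for a, _ in rows)
    n = sum(row_tot)
    denom = comb(n, c1)

    def prob(ks):
        num = 1
        for rt, k in zip(row_tot, ks):
            num *= comb(rt, k)
        return Fraction(num, denom)

    obs = prob([a for a, _ in rows])

    def tables(i, remaining):
        if i == len(rows) - 1:
            if remaining <= row_tot[i]:
                yield [remaining]
            return
        cap = sum(row_tot[i + 1 :])
        for k in range(max(0, remaining - cap), min(row_tot[i], remaining) + 1):
            for rest in tables(i + 1, remaining - k):
                yield [k] + rest

    return float(sum(prob(ks) for ks in tables(0, c1) if prob(ks) <= obs))


def test_hypergeometric_pmf_single_draw_symmetry():
    assert hypergeometric_pmf(1, 2, 1, 1) == pytest.approx(0.5)


def test_hypergeometric_pmf_normalizes_at_study_scale():
    total = sum(hypergeometric_pmf(k, 258, 104, 45) for k in range(0, 46))
    assert total == pytest.approx(1.0, abs=1e-12)


def test_hypergeometric_pmf_out_of_support_is_zero():
    assert hypergeometric_pmf(10, 20, 5, 5) == 0.0
    assert hypergeometric_pmf(-1, 20, 5, 5) == 0.0


def test_hypergeometric_pmf_matches_rational_oracle():
    rng = np.random.default_rng(7)
    for _ in range(200):
        n_total = int(rng.integers(1, 61))
        K = int(rng.integers(0, n_total + 1))
        n_draw = int(rng.integers(0, n_total + 1))
        denom = comb(n_total, n_draw)
        for k in range(max(0, n_draw + K - n_total), min(K, n_draw) + 1):
            exact = comb(K, k) * comb(n_total - K, n_draw - k) / denom
            assert hypergeometric_pmf(k, n_total, K, n_draw) == pytest.approx(
                exact, rel=1e-12
            )


def test_fisher_balanced_table_is_one():
    assert fisher_exact_two_sided(ContingencyTable2x2(1, 1, 1, 1)) == 1.0


def test_fisher_degenerate_margin_is_one():
    assert fisher_exact_two_sided(ContingencyTable2x2(0, 0, 3, 4)) == 1.0
    assert fisher_exact_two_sided(ContingencyTable2x2(0, 3, 0, 4)) == 1.0


@pytest.mark.parametrize(
    "table, printed",
    [
        ((27, 77, 18, 136), 0.004),
        ((27, 77, 11, 19), 0.259),
        ((11, 19, 18, 136), 0.002),
        ((81, 23, 94, 60), 0.005),
        ((81, 23, 17, 13), 0.034),
        ((17, 13, 94, 60), 0.687),
    ],
)
def test_fisher_reproduces_published_p_values(table, printed):
    p = fisher_exact_two_sided(ContingencyTable2x2(*table))
    assert round(p, 3) == printed


def test_fisher_matches_rational_oracle_on_random_tables():
    rng = np.random.default_rng(11)
    checked = 0
    while checked < 300:
        cells = rng.multinomial(int(rng.integers(4, 41)), [0.25] * 4)
        t = ContingencyTable2x2(*(int(x) for x in cells))
        if t.degenerate:
            continue
        assert fisher_exact_two_sided(t) == pytest.approx(
            rational_fisher(t.a, t.b, t.c, t.d), abs=1e-10
        )
        checked += 1


def test_fisher_matches_scipy_cross_check():
    rng = np.random.default_rng(13)
    for _ in range(100):
        cells = [int(x) for x in rng.integers(0, 30, size=4)]
        t = ContingencyTable2x2(*cells) if sum(cells) else None
        if t is None or t.degenerate:
            continue
        assert fisher_exact_two_sided(t) == pytest.approx(
            scipy_fisher(t.as_rows())[1], rel=1e-9, abs=1e-12
        )


def test_fisher_invariant_under_table_symmetries():
    rng = np.random.default_rng(17)
    for _ in range(50):
        a, b, c, d = (int(x) for x in rng.integers(1, 25, size=4))
        p = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d))
        assert fisher_exact_two_sided(ContingencyTable2x2(c, d, a, b)) == pytest.approx(p)
        assert fisher_exact_two_sided(ContingencyTable2x2(b, a, d, c)) == pytest.approx(p)
        assert fisher_exact_two_sided(ContingencyTable2x2(a, c, b, d)) == pytest.approx(p)


def test_freeman_halton_matches_rational_oracle():
    rng = np.random.default_rng(19)
    for _ in range(40):
        rows = [
            (int(rng.integers(0, 11)), int(rng.integers(0, 11))) for _ in range(3)
        ]
        if any(a + b == 0 for a, b in rows):
            continue
        c1 = sum(a for a, _ in rows)
        if c1 == 0 or c1 == sum(a + b for a, b in rows):
            continue
        assert freeman_halton_exact(rows) == pytest.approx(
            rational_freeman_halton(rows), abs=1e-10
        )


def test_freeman_halton_on_published_counts_is_significant():
    # omnibus across the three groups, both features
    assert freeman_halton_exact([(27, 77), (11, 19), (18, 136)]) < 0.05
    assert freeman_halton_exact([(81, 23), (17, 13), (94, 60)]) < 0.05


# ---------------------------------------------------------------------------
# Allele counting
# ---------------------------------------------------------------------------


def hap(a, b):
    return DQHaplotype(
        normalize_allele_name(f"DQA1*{a}"), normalize_allele_name(f"DQB1*{b}")
    )


def test_single_dq25_homozygote_counts_two(serotable):
    h = hap("05:01", "02:01")
    cohort = Cohort([Individual("p", Group.PMN, h, h, PLA2R1Genotype("AA"))])
    assert count_haplotype_alleles(cohort, "pMN", "DQ2.5", serotable) == (2, 0)


def test_single_heterozygote_risk_alleles():
    h = hap("05:01", "02:01")
    cohort = Cohort([Individual("p", Group.PMN, h, h, PLA2R1Genotype("AG"))])
    assert count_risk_alleles(cohort, "pMN") == (1, 1)


def test_empty_group_counts_are_explicit_zeros(serotable):
    cohort = Cohort([])
    assert count_haplotype_alleles(cohort, "pMN", "DQ2.5", serotable) == (0, 0)
    assert count_risk_alleles(cohort, "pMN") == (0, 0)


def test_counts_satisfy_complement_identity(serotable, table1_cohort):
    for group in ("pMN", "sMN", "control"):
        n = len(table1_cohort.by_group(group))
        c, comp = count_haplotype_alleles(table1_cohort, group, "DQ2.5", serotable)
        assert c + comp == 2 * n
        a, g = count_risk_alleles(table1_cohort, group)
        assert a + g == 2 * n


def test_pairwise_tests_flag_bonferroni_threshold(serotable, table1_cohort):
    summary = summarize_allele_counts(table1_cohort, "DQ2.5", serotable)
    results = pairwise_group_tests(summary, alpha=0.05, m_tests=3)
    assert len(results) == 6
    by_key = {(r.feature, r.group_pair): r for r in results}
    snp_pmn_smn = by_key[("PLA2R1 risk allele (rs4664308)", ("pMN", "sMN"))]
    # p = 0.034 exceeds the unrounded 0.05/3 threshold
    assert snp_pmn_smn.threshold == pytest.approx(0.05 / 3)
    assert not snp_pmn_smn.significant
    for r in results:
        assert (r.p_value < r.threshold) == r.significant


def test_pairwise_tests_mark_empty_group_degenerate(serotable):
    h = hap("05:01", "02:01")
    cohort = Cohort(
        [
            Individual("p", Group.PMN, h, h, PLA2R1Genotype("AA")),
            Individual("c", Group.CONTROL, h, h, PLA2R1Genotype("GG")),
        ]
    )
    summary = summarize_allele_counts(cohort, "DQ2.5", serotable)
    results = pairwise_group_tests(summary)
    smn_pairs = [r for r in results if "sMN" in r.group_pair]
    assert smn_pairs and all(r.degenerate and r.p_value == 1.0 for r in smn_pairs)
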