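"""Allele counting and exact association tests on 2x2 (and 3x2) tables.

Counting is at chromosome resolution: each individual contributes two
haplotypes, so a group of N individuals has a denominator of 2N both for
serotype-labelled haplotypes and for rs4664308 alleles (A dose 2/1/0 for
AA/AG/GG).

The two-sided Fisher exact test uses the minimum-likelihood convention:
with all margins fixed, p is the sum of hypergeometric probabilities of
every table whose probability does not exceed that of the observed table
(within a small relative tolerance for floating-point ties). The same
machinery generalizes to a 3x2 omnibus (Freeman-Halton style) test by
full enumeration over tables with fixed margins. Probabilities are
computed in log space via log-gamma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .cohort import Cohort, Group
from .serotype import SerotypeTable, label_haplotype

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "AlleleCountSummary",
    "count_haplotype_alleles",
    "count_risk_alleles",
    "summarize_allele_counts",
    "hypergeometric_pmf",
    "fisher_exact_two_sided",
    "freeman_halton_exact",
    "pairwise_group_tests",
]

# relative tolerance when comparing table probabilities with the observed
# one: floating-point ties at the observed table must count as "as extreme"
PMF_TIE_RTOL = 1e-7

GROUP_PAIRS = (
    (Group.PMN, Group.CONTROL),
    (Group.PMN, Group.SMN),
    (Group.SMN, Group.CONTROL),
)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows = groups, columns = feature / complement."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"counts must be non-negative integers, got {v!r}")
        if self.n == 0:
            raise ValueError("contingency table is empty")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def degenerate(self) -> bool:
        """A zero row or column margin: the table carries no information."""
        return (
            self.a + self.b == 0
            or self.c + self.d == 0
            or self.a + self.c == 0
            or self.b + self.d == 0
        )

    def as_rows(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]


@dataclass(frozen=True)
class TestResult:
    """A single exact-test outcome with its multiplicity-corrected threshold."""

    feature: str
    group_pair: tuple[str, str]
    table: Optional[ContingencyTable2x2]
    p_value: float
    alpha: float
    m_tests: int
    degenerate: bool = False

    @property
    def threshold(self) -> float:
        return self.alpha / self.m_tests

    @property
    def significant(self) -> bool:
        return self.p_value < self.threshold


# ---------------------------------------------------------------------------
# Allele counting
# ---------------------------------------------------------------------------


def count_haplotype_alleles(
    cohort: Cohort, group: Group | str, serotype: str, table: SerotypeTable
) -> tuple[int, int]:
    """(count, complement) of haplotypes labelled ``serotype`` in a group.

    Each individual contributes both haplotypes, so count + complement
    equals twice the group size. An empty group yields (0, 0).
    """
    members = cohort.by_group(group)
    count = sum(
        (label_haplotype(ind.hap1, table) == serotype)
        + (label_haplotype(ind.hap2, table) == serotype)
        for ind in members
    )
    return count, 2 * len(members) - count


def count_risk_alleles(cohort: Cohort, group: Group | str) -> tuple[int, int]:
    """(A count, G count) of rs4664308 alleles in a group; sums to 2N."""
    members = cohort.by_group(group)
    count_a = sum(ind.pla2r1.risk_dose for ind in members)
    return count_a, 2 * len(members) - count_a


@dataclass
class AlleleCountSummary:
    """Per-group haplotype-serotype and risk-allele counts (Table-style)."""

    serotype: str
    group_sizes: dict[str, int]
    haplotype_counts: dict[str, tuple[int, int]]
    risk_allele_counts: dict[str, tuple[int, int]]

    @property
    def empty_groups(self) -> set[str]:
        return {g for g, n in self.group_sizes.items() if n == 0}


def summarize_allele_counts(
    cohort: Cohort, serotype: str, table: SerotypeTable
) -> AlleleCountSummary:
    sizes = cohort.group_sizes()
    return AlleleCountSummary(
        serotype=serotype,
        group_sizes=sizes,
        haplotype_counts={
            g.value: count_haplotype_alleles(cohort, g, serotype, table)
            for g in Group
        },
        risk_allele_counts={
            g.value: count_risk_alleles(cohort, g) for g in Group
        },
    )


# ---------------------------------------------------------------------------
# Hypergeometric kernel
# ---------------------------------------------------------------------------


def _log_choose(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def hypergeometric_pmf(k: int, n_total: int, K_feature: int, n_draw: int) -> float:
    """P(k feature items in a draw of n_draw from n_total holding K_feature).

    Computed in log space; returns 0.0 for k outside the support
    [max(0, n_draw + K_feature - n_total), min(K_feature, n_draw)].
    """
    if not (0 <= K_feature <= n_total and 0 <= n_draw <= n_total):
        raise ValueError("require 0 <= K_feature, n_draw <= n_total")
    lo = max(0, n_draw + K_feature - n_total)
    hi = min(K_feature, n_draw)
    if not (lo <= k <= hi):
        return 0.0
    return math.exp(
        _log_choose(K_feature, k)
        + _log_choose(n_total - K_feature, n_draw - k)
        - _log_choose(n_total, n_draw)
    )


def fisher_exact_two_sided(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value (minimum-likelihood convention).

    Sums the conditional hypergeometric probabilities of every table with
    the observed margins whose probability is <= the observed table's
    (relative tie tolerance ``PMF_TIE_RTOL``). A degenerate table (zero
    row or column) returns 1.0 by convention.
    """
    if t.degenerate:
        return 1.0
    n_total = t.n
    K = t.a + t.c  # feature column margin
    n_draw = t.a + t.b  # first row margin
    p_obs = hypergeometric_pmf(t.a, n_total, K, n_draw)
    cutoff = p_obs * (1.0 + PMF_TIE_RTOL)
    lo = max(0, n_draw + K - n_total)
    hi = min(K, n_draw)
    p = 0.0
    for k in range(lo, hi + 1):
        pk = hypergeometric_pmf(k, n_total, K, n_draw)
        if pk <= cutoff:
            p += pk
    return _clamp_p(p)


def _clamp_p(p: float) -> float:
    """Clamp to (0, 1]; snap float-accumulation residue at the top (a full
    support sums to exactly 1 in exact arithmetic)."""
    if p >= 1.0 - 1e-12:
        return 1.0
    return p


def freeman_halton_exact(rows: Sequence[tuple[int, int]]) -> float:
    """Exact omnibus test for an R x 2 table by full enumeration.

    Generalizes the minimum-likelihood two-sided Fisher test: with all
    margins fixed, sums the multivariate hypergeometric probabilities of
    every table no more probable than the observed one. Intended for the
    3-group (pMN / sMN / control) omnibus comparison; enumeration is over
    the first column's per-row counts.
    """
    rows = [tuple(r) for r in rows]
    if any(len(r) != 2 or min(r) < 0 for r in rows):
        raise ValueError("rows must be non-negative (feature, complement) pairs")
    row_tot = [a + b for a, b in rows]
    col1 = sum(a for a, _ in rows)
    n = sum(row_tot)
    if n == 0 or col1 == 0 or col1 == n or any(r == 0 for r in row_tot):
        return 1.0

    log_denom = _log_choose(n, col1)

    def log_prob(ks: Sequence[int]) -> float:
        return sum(_log_choose(row_tot[i], ks[i]) for i in range(len(rows))) - log_denom

    obs = [a for a, _ in rows]
    lp_obs = log_prob(obs)
    cutoff = lp_obs + math.log1p(PMF_TIE_RTOL)

    p = 0.0

    def recurse(i: int, remaining: int, ks: list[int]) -> None:
        nonlocal p
        if i == len(rows) - 1:
            if remaining <= row_tot[i]:
                lp = log_prob(ks + [remaining])
                if lp <= cutoff:
                    p += math.exp(lp)
            return
        tail_cap = sum(row_tot[i + 1 :])
        lo = max(0, remaining - tail_cap)
        hi = min(row_tot[i], remaining)
        for k in range(lo, hi + 1):
            recurse(i + 1, remaining - k, ks + [k])

    recurse(0, col1, [])
    return _clamp_p(p)


# ---------------------------------------------------------------------------
# Pairwise group tests
# ---------------------------------------------------------------------------


def pairwise_group_tests(
    summary: AlleleCountSummary, alpha: float = 0.05, m_tests: int = 3
) -> list[TestResult]:
    """Fisher exact tests for (pMN-control, pMN-sMN, sMN-control) per feature.

    Features are the serotype-haplotype count and the rs4664308 A-allele
    count; the Bonferroni threshold alpha/m_tests is applied unrounded and
    uniformly. Pairs involving an empty group yield a degenerate result
    with p = 1.0.
    """
    results: list[TestResult] = []
    features = (
        (f"HLA-{summary.serotype} haplotype", summary.haplotype_counts),
        ("PLA2R1 risk allele (rs4664308)", summary.risk_allele_counts),
    )
    for feature_name, counts in features:
        for g1, g2 in GROUP_PAIRS:
            (a, b), (c, d) = counts[g1.value], counts[g2.value]
            if (a + b == 0) or (c + d == 0):
                # empty group: no informative table, p = 1 by convention
                results.append(
                    TestResult(
                        feature=feature_name,
                        group_pair=(g1.value, g2.value),
                        table=None,
                        p_value=1.0,
                        alpha=alpha,
                        m_tests=m_tests,
                        degenerate=True,
                    )
                )
                continue
            table = ContingencyTable2x2(a, b, c, d)
            results.append(
                TestResult(
                    feature=feature_name,
                    group_pair=(g1.value, g2.value),
                    table=table,
                    p_value=fisher_exact_two_sided(table),
                    alpha=alpha,
                    m_tests=m_tests,
                    degenerate=table.degenerate,
                )
            )
    return results
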