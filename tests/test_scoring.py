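"""Risk-score formula, carrier frequencies, ranking, and the crosstab."""

import pytest

from dqrisk import (
    Cohort,
    GenotypeFreqs,
    carrier_genotype_freqs,
    crosstab_genotype_phenotype,
    rank_combinations,
    risk_score,
    table1_fixture,
)
from dqrisk.cohort import (
    DQHaplotype,
    Group,
    Individual,
    Phenotype,
    PLA2R1Genotype,
    normalize_allele_name,
)


def hap(a, b):
    return DQHaplotype(
        normalize_allele_name(f"DQA1*{a}"), normalize_allele_name(f"DQB1*{b}")
    )


DQ25 = hap("05:01", "02:01")
DQ75 = hap("05:05", "03:01")
OTHER = hap("01:01", "05:01")


def ind(i, group, h1, h2, gt):
    return Individual(str(i), group, h1, h2, PLA2R1Genotype(gt))


def test_carrier_freqs_recover_known_mix(serotable):
    cohort = Cohort(
        [
            ind(1, Group.PMN, DQ25, DQ25, "AA"),
            ind(2, Group.PMN, DQ25, DQ25, "AG"),
            ind(3, Group.PMN, DQ75, DQ75, "GG"),  # not a carrier
        ]
    )
    f = carrier_genotype_freqs(cohort, "pMN", "DQ2.5/DQ2.5", serotable)
    assert (f.f_AA, f.f_AG, f.f_GG, f.n_carriers) == (0.5, 0.5, 0.0, 2)


def test_zero_carriers_yield_zero_freqs_not_nan(serotable):
    cohort = Cohort([ind(1, Group.PMN, DQ75, DQ75, "AA")])
    f = carrier_genotype_freqs(cohort, "pMN", "DQ2.5/DQ2.5", serotable)
    assert f == GenotypeFreqs.zero()


def test_group_denominator_mode(serotable):
    cohort = Cohort(
        [
            ind(1, Group.PMN, DQ25, DQ25, "AA"),
            ind(2, Group.PMN, DQ75, DQ75, "AA"),
        ]
    )
    f = carrier_genotype_freqs(
        cohort, "pMN", "DQ2.5/DQ2.5", serotable, denominator="group"
    )
    assert f.f_AA == pytest.approx(0.5)
    assert f.n_carriers == 1


def test_score_formula_and_extremes():
    zero = GenotypeFreqs.zero()
    assert risk_score("x", zero, zero).score == 0.0
    assert not risk_score("x", zero, zero).defined

    all_ag = GenotypeFreqs(0.0, 1.0, 0.0, 5)
    all_gg = GenotypeFreqs(0.0, 0.0, 1.0, 5)
    all_aa = GenotypeFreqs(1.0, 0.0, 0.0, 5)
    assert risk_score("x", all_ag, all_gg).score == pytest.approx(2.0)  # max
    assert risk_score("x", all_gg, all_aa).score == pytest.approx(-2.0)  # min

    mixed_p = GenotypeFreqs(0.25, 0.5, 0.25, 8)
    mixed_c = GenotypeFreqs(0.5, 0.25, 0.25, 8)
    expected = 0.25 + 2 * 0.5 - 2 * 0.5 - 0.25
    assert risk_score("x", mixed_p, mixed_c).score == pytest.approx(expected)


def test_score_monotonic_in_frequency_shifts():
    base_p = GenotypeFreqs(0.2, 0.3, 0.5, 10)
    base_c = GenotypeFreqs(0.2, 0.3, 0.5, 10)
    s0 = risk_score("x", base_p, base_c).score
    delta = 0.2
    # moving pMN mass from GG to AG raises the score by exactly 2*delta
    shifted_p = GenotypeFreqs(0.2, 0.3 + delta, 0.5 - delta, 10)
    assert risk_score("x", shifted_p, base_c).score - s0 == pytest.approx(2 * delta)
    # moving control mass from GG to AA lowers it by exactly 2*delta
    shifted_c = GenotypeFreqs(0.2 + delta, 0.3, 0.5 - delta, 10)
    assert risk_score("x", base_p, shifted_c).score - s0 == pytest.approx(-2 * delta)


def test_low_confidence_flag_for_one_sided_carriers():
    pmn = GenotypeFreqs(1.0, 0.0, 0.0, 3)
    res = risk_score("x", pmn, GenotypeFreqs.zero())
    assert res.defined and res.low_confidence


def test_rank_requires_pmn_and_control(serotable):
    cohort = Cohort([ind(1, Group.PMN, DQ25, DQ25, "AA")])
    with pytest.raises(ValueError, match="control"):
        rank_combinations(cohort, serotable)


def test_rank_all_gg_scores_zero(serotable):
    cohort = Cohort(
        [
            ind(1, Group.PMN, DQ25, DQ25, "GG"),
            ind(2, Group.PMN, DQ75, OTHER, "GG"),
            ind(3, Group.CONTROL, DQ25, DQ75, "GG"),
        ]
    )
    results = rank_combinations(cohort, serotable)
    assert results and all(r.score == 0.0 for r in results)
    # deterministic tie-break: label-sorted when scores tie
    assert [r.combination for r in results] == sorted(r.combination for r in results)


def test_rank_orders_risk_above_protective(serotable):
    # DQ2.5/DQ2.5 pMN carriers AG-heavy (risk); DQ7.5/DQ7.5 control AA (protective)
    cohort = Cohort(
        [
            ind(1, Group.PMN, DQ25, DQ25, "AG"),
            ind(2, Group.PMN, DQ25, DQ25, "AG"),
            ind(3, Group.PMN, DQ75, DQ75, "GG"),
            ind(4, Group.CONTROL, DQ25, DQ25, "GG"),
            ind(5, Group.CONTROL, DQ75, DQ75, "AA"),
            ind(6, Group.CONTROL, DQ75, DQ75, "AA"),
        ]
    )
    results = rank_combinations(cohort, serotable)
    assert results[0].combination == "DQ2.5/DQ2.5"
    assert results[0].score > 0
    assert results[-1].combination == "DQ7.5/DQ7.5"
    assert results[-1].score < 0


def test_smn_individuals_never_enter_scores(serotable):
    base = [
        ind(1, Group.PMN, DQ25, DQ25, "AG"),
        ind(2, Group.CONTROL, DQ25, DQ25, "GG"),
    ]
    with_smn = base + [ind(3, Group.SMN, DQ25, DQ25, "AA")]
    r1 = rank_combinations(Cohort(base), serotable)
    r2 = rank_combinations(Cohort(with_smn), serotable)
    assert [(r.combination, r.score) for r in r1] == [
        (r.combination, r.score) for r in r2
    ]


# ---------------------------------------------------------------------------
# Genotype-phenotype crosstab
# ---------------------------------------------------------------------------


def test_crosstab_published_positivity_rates(table1_cohort):
    ct = crosstab_genotype_phenotype(table1_cohort)
    pmn = ct.per_group["pMN"]
    assert round(pmn["serology_pct_positive"], 1) == 76.5
    assert pmn["staining_pct_positive"] == pytest.approx(80.0)
    smn = ct.per_group["sMN"]
    assert smn["any_positive"] == 0 and smn["any_tested"] > 0


def test_crosstab_all_not_done_has_no_division_errors():
    cohort = Cohort([ind(1, Group.PMN, DQ25, DQ25, "AA")])
    ct = crosstab_genotype_phenotype(cohort)
    assert ct.per_group["pMN"]["serology_pct_positive"] is None
    assert ct.by_genotype["AA"]["not_done"] == 1
    assert sum(v for row in ct.by_genotype.values() for v in row.values()) == 1


def test_crosstab_counts_partition_cohort(table1_cohort):
    ct = crosstab_genotype_phenotype(table1_cohort)
    total = sum(v for row in ct.by_genotype.values() for v in row.values())
    assert total == len(table1_cohort)
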