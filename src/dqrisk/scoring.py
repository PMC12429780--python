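"""PLA2R1-genotype-weighted risk scoring of HLA-DQ combinations.

The biological premise: the rs4664308 A allele drives illegitimate
PLA2R1 expression in the kidney. A primary-MN patient who developed
disease while carrying only one risk allele (AG) points to a permissive
("risk") HLA-DQ combination — disease arose despite low antigen dose —
while a healthy control carrying two risk alleles (AA) points to a
protective combination — no disease despite high antigen dose. Each
HLA-DQ combination is therefore scored from the rs4664308 genotype
frequencies among its carriers in the pMN and control groups:

    score = f(pMN_AA) + 2 f(pMN_AG) - 2 f(control_AA) - f(control_AG)

Positive scores mark risk combinations, negative scores protective ones;
the score is bounded in [-2, 2]. Frequencies are computed among the
carriers of the combination within each group (each carrier counted
once, however many dimers realize the combination). Note the asymmetric
weighting means the score is centred on zero under a shared genotype
distribution only when f(AA) = f(AG) in that distribution; its null
expectation is f(AG) - f(AA).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

from .cohort import Cohort, Group, Individual, Phenotype
from .serotype import (
    CombinationMode,
    SerotypeTable,
    combination_key,
    profile_individual,
)

__all__ = [
    "GenotypeFreqs",
    "RiskScoreResult",
    "carrier_genotype_freqs",
    "risk_score",
    "rank_combinations",
    "crosstab_genotype_phenotype",
]

Denominator = Literal["carriers", "group"]


@dataclass(frozen=True)
class GenotypeFreqs:
    """rs4664308 genotype frequencies among carriers of one combination."""

    f_AA: float
    f_AG: float
    f_GG: float
    n_carriers: int

    def __post_init__(self) -> None:
        total = self.f_AA + self.f_AG + self.f_GG
        if total > 1.0 + 1e-9:
            raise ValueError(f"genotype frequencies sum to {total} > 1")
        if self.n_carriers == 0 and total != 0.0:
            raise ValueError("zero carriers must have all-zero frequencies")
        for f in (self.f_AA, self.f_AG, self.f_GG):
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"frequency {f} outside [0, 1]")

    @classmethod
    def zero(cls) -> "GenotypeFreqs":
        return cls(0.0, 0.0, 0.0, 0)


@dataclass(frozen=True)
class RiskScoreResult:
    combination: str
    pmn_freqs: GenotypeFreqs
    control_freqs: GenotypeFreqs
    score: float
    defined: bool
    low_confidence: bool = False  # zero carriers in exactly one group

    def __post_init__(self) -> None:
        if self.defined and not (-2.0 <= self.score <= 2.0):
            raise ValueError(f"score {self.score} outside [-2, 2]")


def _combination_keys(
    cohort: Cohort, table: SerotypeTable, mode: CombinationMode
) -> dict[str, str]:
    return {
        ind.id: combination_key(profile_individual(ind, table), mode)
        for ind in cohort
    }


def carrier_genotype_freqs(
    cohort: Cohort,
    group: Group | str,
    combination: str,
    table: SerotypeTable,
    mode: CombinationMode = "haplotype_pair",
    denominator: Denominator = "carriers",
) -> GenotypeFreqs:
    """rs4664308 genotype frequencies among a combination's carriers in a group.

    A carrier is an individual whose combination key equals ``combination``
    (counted once regardless of how many dimers realize it). With
    ``denominator="carriers"`` frequencies are normalized by the carrier
    count; ``denominator="group"`` normalizes by the whole group size
    instead (an alternative sample-size reading). Zero carriers (or an
    empty group) yield all-zero frequencies with n_carriers = 0.
    """
    members = cohort.by_group(group)
    carriers = [
        ind
        for ind in members
        if combination_key(profile_individual(ind, table), mode) == combination
    ]
    if not carriers:
        return GenotypeFreqs.zero()
    denom = len(carriers) if denominator == "carriers" else len(members)
    counts = {"AA": 0, "AG": 0, "GG": 0}
    for ind in carriers:
        counts[ind.pla2r1.value] += 1
    return GenotypeFreqs(
        f_AA=counts["AA"] / denom,
        f_AG=counts["AG"] / denom,
        f_GG=counts["GG"] / denom,
        n_carriers=len(carriers),
    )


def risk_score(
    combination: str, pmn: GenotypeFreqs, control: GenotypeFreqs
) -> RiskScoreResult:
    """Score one combination from its pMN and control genotype frequencies.

    Undefined (score 0, ``defined=False``) when both groups have zero
    carriers; low-confidence when exactly one group has zero carriers
    (that group's terms are 0 by the carrier-frequency definition).
    """
    score = pmn.f_AA + 2.0 * pmn.f_AG - 2.0 * control.f_AA - control.f_AG
    defined = not (pmn.n_carriers == 0 and control.n_carriers == 0)
    return RiskScoreResult(
        combination=combination,
        pmn_freqs=pmn,
        control_freqs=control,
        score=score if defined else 0.0,
        defined=defined,
        low_confidence=defined
        and (pmn.n_carriers == 0 or control.n_carriers == 0),
    )


def rank_combinations(
    cohort: Cohort,
    table: SerotypeTable,
    mode: CombinationMode = "haplotype_pair",
    denominator: Denominator = "carriers",
) -> list[RiskScoreResult]:
    """Score every combination observed in pMN or controls, risk first.

    Sorted by descending score with lexicographic label tie-break for
    determinism. sMN individuals never enter the score (the formula is
    defined on pMN and control frequencies only).
    """
    pmn = cohort.by_group(Group.PMN)
    control = cohort.by_group(Group.CONTROL)
    if not pmn or not control:
        missing = "pMN" if not pmn else "control"
        raise ValueError(f"risk scoring requires a non-empty {missing} group")

    keys = {
        ind.id: combination_key(profile_individual(ind, table), mode)
        for ind in pmn + control
    }
    combos = sorted({keys[ind.id] for ind in pmn} | {keys[ind.id] for ind in control})

    results = []
    for combo in combos:
        res = risk_score(
            combo,
            carrier_genotype_freqs(
                cohort, Group.PMN, combo, table, mode, denominator
            ),
            carrier_genotype_freqs(
                cohort, Group.CONTROL, combo, table, mode, denominator
            ),
        )
        if res.defined:
            results.append(res)
    results.sort(key=lambda r: (-r.score, r.combination))
    return results


# ---------------------------------------------------------------------------
# Genotype vs staining/serology cross-tabulation
# ---------------------------------------------------------------------------


@dataclass
class GenotypePhenotypeCrosstab:
    """Counts of PLA2R1 phenotype positivity stratified by rs4664308 genotype.

    ``by_genotype``: genotype -> {any_positive, none_positive, not_done}
    over the whole cohort, where "any_positive" means staining or serology
    positive and "not_done" means neither assay was performed.
    ``per_group``: group -> per-assay tested / positive counts and percent
    positive among tested (None when nothing was tested).
    """

    by_genotype: dict[str, dict[str, int]]
    per_group: dict[str, dict[str, Optional[float] | int]]


def crosstab_genotype_phenotype(cohort: Cohort) -> GenotypePhenotypeCrosstab:
    by_genotype = {
        g: {"any_positive": 0, "none_positive": 0, "not_done": 0}
        for g in ("AA", "AG", "GG")
    }
    per_group: dict[str, dict] = {}

    for ind in cohort:
        tested = (
            ind.staining is not Phenotype.NOT_DONE
            or ind.serology is not Phenotype.NOT_DONE
        )
        positive = (
            ind.staining is Phenotype.POSITIVE or ind.serology is Phenotype.POSITIVE
        )
        cell = by_genotype[ind.pla2r1.value]
        if not tested:
            cell["not_done"] += 1
        elif positive:
            cell["any_positive"] += 1
        else:
            cell["none_positive"] += 1

    for group in Group:
        members = cohort.by_group(group)
        stats: dict[str, Optional[float] | int] = {}
        for assay in ("staining", "serology"):
            tested = [m for m in members if getattr(m, assay) is not Phenotype.NOT_DONE]
            pos = [m for m in tested if getattr(m, assay) is Phenotype.POSITIVE]
            stats[f"{assay}_tested"] = len(tested)
            stats[f"{assay}_positive"] = len(pos)
            stats[f"{assay}_pct_positive"] = (
                100.0 * len(pos) / len(tested) if tested else None
            )
        any_tested = [
            m
            for m in members
            if m.staining is not Phenotype.NOT_DONE
            or m.serology is not Phenotype.NOT_DONE
        ]
        any_pos = [
            m
            for m in any_tested
            if m.staining is Phenotype.POSITIVE or m.serology is Phenotype.POSITIVE
        ]
        stats["any_tested"] = len(any_tested)
        stats["any_positive"] = len(any_pos)
        stats["any_pct_positive"] = (
            100.0 * len(any_pos) / len(any_tested) if any_tested else None
        )
        per_group[group.value] = stats

    return GenotypePhenotypeCrosstab(by_genotype=by_genotype, per_group=per_group)
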