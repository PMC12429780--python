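"""Seeded synthetic case-control cohorts with the structure the analysis assumes.

The study's individual-level data are unreleased, so every stage is
exercised on generated cohorts instead. Two kinds are provided:

* :func:`generate_cohort` — stochastic cohorts from a
  :class:`SyntheticConfig`: each individual draws two haplotypes
  independently from the group's pool, then an rs4664308 genotype from
  the group's baseline distribution unless an explicit effect override
  matches the individual's HLA-DQ combination. The genotype is otherwise
  independent of HLA, which makes the scoring null hold by construction.
* :func:`table1_fixture` — a deterministic cohort that reproduces the
  published per-group haplotype and allele counts exactly (52 pMN /
  15 sMN / 77 controls; DQ2.5 haplotypes 27, 11, 18 of 104, 30, 154;
  rs4664308 A alleles 81, 17, 94), with staining/serology assignments
  matching the printed positivity counts.

A single integer seed drives one generator stream; per-individual draws
consume it in a fixed order (hap1, hap2, genotype; groups in pMN, sMN,
control order), so cohorts are stable across platforms.
"""

from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import dataclass, field
from itertools import accumulate
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .cohort import (
    Cohort,
    DQHaplotype,
    Group,
    Individual,
    Phenotype,
    PLA2R1Genotype,
    normalize_allele_name,
)
from .serotype import (
    CombinationMode,
    SerotypeTable,
    combination_key,
    default_serotype_table,
    profile_individual,
)

__all__ = [
    "SyntheticConfig",
    "GenotypeEffect",
    "GenerationReport",
    "generate_cohort",
    "default_config",
    "neutral_config",
    "implant_effect_fixture",
    "table1_fixture",
    "load_config",
]

_GROUP_ORDER = (Group.PMN, Group.SMN, Group.CONTROL)
_GENOTYPES = ("AA", "AG", "GG")


def _hap(dqa1: str, dqb1: str) -> DQHaplotype:
    return DQHaplotype(
        normalize_allele_name(f"DQA1*{dqa1}"), normalize_allele_name(f"DQB1*{dqb1}")
    )


@dataclass(frozen=True)
class GenotypeEffect:
    """Override of the baseline rs4664308 distribution for one combination.

    Applies to individuals of ``group`` whose combination key equals
    ``combination``; ``dist`` is (P(AA), P(AG), P(GG)).
    """

    combination: str
    group: str
    dist: tuple[float, float, float]


@dataclass
class SyntheticConfig:
    """Everything :func:`generate_cohort` needs, with validated probabilities.

    ``haplotype_pool`` maps each haplotype to a per-group frequency;
    frequencies must sum to 1 within each group. ``genotype_dist`` gives
    per-group baseline (P(AA), P(AG), P(GG)).
    """

    group_sizes: dict[str, int]
    haplotype_pool: list[tuple[DQHaplotype, dict[str, float]]]
    genotype_dist: dict[str, tuple[float, float, float]]
    effects: list[GenotypeEffect] = field(default_factory=list)
    seed: int = 0
    combination_mode: CombinationMode = "haplotype_pair"

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            Group(g)
            if n < 0:
                raise ValueError(f"negative group size for {g}")
        for g in self.group_sizes:
            total = sum(freqs.get(g, 0.0) for _, freqs in self.haplotype_pool)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"haplotype frequencies for group {g} sum to {total}, not 1"
                )
            dist = self.genotype_dist[g]
            if len(dist) != 3 or min(dist) < 0 or abs(sum(dist) - 1.0) > 1e-9:
                raise ValueError(f"invalid genotype distribution for group {g}: {dist}")
        for eff in self.effects:
            Group(eff.group)
            if len(eff.dist) != 3 or min(eff.dist) < 0 or abs(sum(eff.dist) - 1.0) > 1e-9:
                raise ValueError(f"invalid effect distribution: {eff}")


@dataclass
class GenerationReport:
    """Realized counts of one generated cohort, for auditing the draw."""

    seed: int
    group_sizes: dict[str, int]
    haplotype_label_counts: dict[str, dict[str, int]]
    genotype_counts: dict[str, dict[str, int]]
    combination_carrier_counts: dict[str, dict[str, int]]

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _draw(rng: np.random.Generator, cum: list[float]) -> int:
    return bisect_right(cum, rng.random())


def generate_cohort(
    config: SyntheticConfig,
    seed: Optional[int] = None,
    table: Optional[SerotypeTable] = None,
) -> tuple[Cohort, GenerationReport]:
    """Draw a cohort from the configured distributions; identical seeds
    (and configs) give identical cohorts."""
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    if table is None:
        table = default_serotype_table()

    haps = [h for h, _ in config.haplotype_pool]
    cum_by_group = {
        g: list(accumulate(freqs.get(g, 0.0) for _, freqs in config.haplotype_pool))
        for g in config.group_sizes
    }
    geno_cum = {g: list(accumulate(d)) for g, d in config.genotype_dist.items()}
    effect_map = {(e.combination, e.group): list(accumulate(e.dist)) for e in config.effects}

    individuals: list[Individual] = []
    hap_counts: dict[str, dict[str, int]] = {}
    geno_counts: dict[str, dict[str, int]] = {}
    combo_counts: dict[str, dict[str, int]] = {}

    for group in _GROUP_ORDER:
        g = group.value
        n = config.group_sizes.get(g, 0)
        hap_counts[g] = {}
        geno_counts[g] = {gt: 0 for gt in _GENOTYPES}
        combo_counts[g] = {}
        for i in range(n):
            hap1 = haps[_draw(rng, cum_by_group[g])]
            hap2 = haps[_draw(rng, cum_by_group[g])]
            ind = Individual(
                id=f"{g}_{i:04d}",
                group=group,
                hap1=hap1,
                hap2=hap2,
                pla2r1=PLA2R1Genotype("AA"),  # placeholder, replaced below
            )
            combo = combination_key(
                profile_individual(ind, table), config.combination_mode
            )
            cum = effect_map.get((combo, g), geno_cum[g])
            genotype = _GENOTYPES[_draw(rng, cum)]
            ind = Individual(
                id=ind.id,
                group=group,
                hap1=hap1,
                hap2=hap2,
                pla2r1=PLA2R1Genotype(genotype),
            )
            individuals.append(ind)

            prof = profile_individual(ind, table)
            for lab in prof.haplotype_labels:
                hap_counts[g][lab] = hap_counts[g].get(lab, 0) + 1
            geno_counts[g][genotype] += 1
            combo_counts[g][combo] = combo_counts[g].get(combo, 0) + 1

    report = GenerationReport(
        seed=seed,
        group_sizes=dict(config.group_sizes),
        haplotype_label_counts=hap_counts,
        genotype_counts=geno_counts,
        combination_carrier_counts=combo_counts,
    )
    return Cohort(individuals), report


# ---------------------------------------------------------------------------
# Shipped configurations
# ---------------------------------------------------------------------------

# Haplotypes named in the study plus two common European "other" haplotypes;
# relative weights of the non-DQ2.5 pool mass are fixed plausible values
# (the study prints only the DQ2.5 marginal).
_POOL_HAPLOTYPES: list[tuple[DQHaplotype, float]] = [
    (_hap("05:05", "03:01"), 0.20),  # DQ7.5
    (_hap("01:02", "06:02"), 0.18),  # DQ6.2
    (_hap("03:01", "03:02"), 0.12),  # DQ8.1
    (_hap("02:01", "02:02"), 0.08),  # DQ2.2
    (_hap("01:01", "05:01"), 0.22),  # other
    (_hap("04:01", "04:02"), 0.20),  # other
]
_DQ25_HAP = _hap("05:01", "02:01")

# published per-group DQ2.5 haplotype fractions and A-allele frequencies
_DQ25_FRACTION = {"pMN": 27 / 104, "sMN": 11 / 30, "control": 18 / 154}
_A_FREQ = {"pMN": 81 / 104, "sMN": 17 / 30, "control": 94 / 154}
_GROUP_SIZES = {"pMN": 52, "sMN": 15, "control": 77}


def default_config(seed: int = 0) -> SyntheticConfig:
    """Cohort emulating the study: published group sizes, DQ2.5 haplotype
    fractions, and Hardy-Weinberg rs4664308 genotypes at the published
    per-group A-allele frequencies."""
    pool: list[tuple[DQHaplotype, dict[str, float]]] = [
        (_DQ25_HAP, dict(_DQ25_FRACTION))
    ]
    for hap, w in _POOL_HAPLOTYPES:
        pool.append(
            (hap, {g: w * (1.0 - _DQ25_FRACTION[g]) for g in _GROUP_SIZES})
        )
    genotype_dist = {
        g: (p * p, 2 * p * (1 - p), (1 - p) * (1 - p))
        for g, p in ((g, _A_FREQ[g]) for g in _GROUP_SIZES)
    }
    return SyntheticConfig(
        group_sizes=dict(_GROUP_SIZES),
        haplotype_pool=pool,
        genotype_dist=genotype_dist,
        seed=seed,
    )


# Neutral and implant fixtures use a two-haplotype pool so every combination
# has enough carriers per group for its score to be informative: with rare
# combinations a single AG carrier saturates the score at 2 and rank
# recovery is not identifiable (the same small-sample limit the study
# itself reports for rare combinations). The neutral genotype distribution
# has P(AA) = P(AG) (Hardy-Weinberg at A frequency 2/3), the regime in
# which the score's null expectation is exactly zero.
_NEUTRAL_DIST = (0.4, 0.4, 0.2)
_TWO_HAP_POOL: list[tuple[DQHaplotype, dict[str, float]]] = [
    (_DQ25_HAP, {g: 0.5 for g in _GROUP_SIZES}),
    (_hap("05:05", "03:01"), {g: 0.5 for g in _GROUP_SIZES}),
]

IMPLANT_COMBINATION = "DQ2.5/DQ2.5"


def neutral_config(seed: int = 0) -> SyntheticConfig:
    """Genotype independent of group and combination: every combination's
    expected score is zero."""
    return SyntheticConfig(
        group_sizes=dict(_GROUP_SIZES),
        haplotype_pool=[(h, dict(f)) for h, f in _TWO_HAP_POOL],
        genotype_dist={g: _NEUTRAL_DIST for g in _GROUP_SIZES},
        seed=seed,
    )


def implant_effect_fixture(kind: str, seed: int = 0) -> SyntheticConfig:
    """Neutral config plus one maximal implanted effect on DQ2.5/DQ2.5.

    ``kind="risk"``: every pMN carrier of the combination is AG, the
    genotype pattern the score reads as risk (its pMN term saturates
    at 2). ``kind="protective"``: every control carrier is AA, the
    pattern read as protective (control term saturates at 2).
    """
    cfg = neutral_config(seed)
    if kind == "risk":
        cfg.effects = [GenotypeEffect(IMPLANT_COMBINATION, "pMN", (0.0, 1.0, 0.0))]
    elif kind == "protective":
        cfg.effects = [GenotypeEffect(IMPLANT_COMBINATION, "control", (1.0, 0.0, 0.0))]
    else:
        raise ValueError(f"kind must be 'risk' or 'protective', got {kind!r}")
    return cfg


# ---------------------------------------------------------------------------
# Deterministic published-counts fixture
# ---------------------------------------------------------------------------

# AA/AG/GG splits resolved from the published per-group allele totals by
# maximizing the AG count subject to those totals (the study prints allele
# counts, not genotype counts, for the full cohort):
#   pMN     81 A / 23 G over 52  ->  29 AA, 23 AG, 0 GG
#   sMN     17 A / 13 G over 15  ->   2 AA, 13 AG, 0 GG
#   control 94 A / 60 G over 77  ->  17 AA, 60 AG, 0 GG
_T1_GENOTYPE_SPLITS = {
    "pMN": (29, 23, 0),
    "sMN": (2, 13, 0),
    "control": (17, 60, 0),
}
_T1_DQ25_HAPS = {"pMN": 27, "sMN": 11, "control": 18}
_OTHER_HAP = _hap("01:01", "05:01")


def table1_fixture() -> Cohort:
    """Deterministic cohort reproducing the published Table-style counts.

    Group sizes 52/15/77; DQ2.5 haplotype counts 27, 11, 18 (the rest an
    unlisted "other" haplotype); rs4664308 genotype splits as documented
    above (A-allele totals 81, 17, 94). Staining/serology follow the
    printed positivity: 30 pMN stained (24 positive), 17 pMN
    serology-tested (13 positive); 7 sMN stained and 5 serology-tested,
    all negative; controls untested. DQ2.5 haplotypes and AA genotypes are
    both assigned from the start of each group, so positivity concentrates
    in AA carriers as in the published genotype-phenotype breakdown.
    """
    individuals: list[Individual] = []
    for group in _GROUP_ORDER:
        g = group.value
        n = _GROUP_SIZES[g]
        n_dq25 = _T1_DQ25_HAPS[g]
        slots = [_DQ25_HAP] * n_dq25 + [_OTHER_HAP] * (2 * n - n_dq25)
        n_aa, n_ag, n_gg = _T1_GENOTYPE_SPLITS[g]
        genotypes = ["AA"] * n_aa + ["AG"] * n_ag + ["GG"] * n_gg
        for i in range(n):
            staining = serology = Phenotype.NOT_DONE
            if g == "pMN":
                if i < 24:
                    staining = Phenotype.POSITIVE
                elif i < 30:
                    staining = Phenotype.NEGATIVE
                if i < 13:
                    serology = Phenotype.POSITIVE
                elif i < 17:
                    serology = Phenotype.NEGATIVE
            elif g == "sMN":
                if i < 7:
                    staining = Phenotype.NEGATIVE
                if i < 5:
                    serology = Phenotype.NEGATIVE
            individuals.append(
                Individual(
                    id=f"{g}_{i:04d}",
                    group=group,
                    hap1=slots[2 * i],
                    hap2=slots[2 * i + 1],
                    pla2r1=PLA2R1Genotype(genotypes[i]),
                    staining=staining,
                    serology=serology,
                )
            )
    return Cohort(individuals)


# ---------------------------------------------------------------------------
# Config file round-trip (YAML / JSON)
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> SyntheticConfig:
    """Load a SyntheticConfig from YAML or JSON.

    Schema: group_sizes (map), haplotype_pool (list of
    {dqa1, dqb1, freq: {group: p}}), genotype_dist (map group ->
    [pAA, pAG, pGG]), effects (list of {combination, group,
    dist: [pAA, pAG, pGG]}), seed.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    pool = [
        (_hap(entry["dqa1"], entry["dqb1"]), {k: float(v) for k, v in entry["freq"].items()})
        for entry in data["haplotype_pool"]
    ]
    effects = [
        GenotypeEffect(e["combination"], e["group"], tuple(float(x) for x in e["dist"]))
        for e in data.get("effects", [])
    ]
    return SyntheticConfig(
        group_sizes={k: int(v) for k, v in data["group_sizes"].items()},
        haplotype_pool=pool,
        genotype_dist={
            k: tuple(float(x) for x in v) for k, v in data["genotype_dist"].items()
        },
        effects=effects,
        seed=int(data.get("seed", 0)),
    )
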