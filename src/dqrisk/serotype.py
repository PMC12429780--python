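"""Cis/trans HLA-DQ heterodimer enumeration and serotype labelling.

At the DNA level DQA1 and DQB1 are tightly linked and inherited together
as a haplotype, but at the protein level the alpha and beta chains from
either chromosome combine freely, so an individual's two haplotypes yield
1, 2 or 4 distinct heterodimers — the cis dimers encoded on one
chromosome plus the trans dimers mixing chains across chromosomes.

Serotype identity (DQ2.5, DQ7.5, ...) is a property of the alpha/beta
allele pair, not of the chromosome of origin: the DQ2.5 dimer, for
instance, is DQA1*05:01 paired with DQB1*02:01 or 02:02 in either
configuration. The dimer-to-serotype map is shipped as data (a TSV), not
code, so nomenclature refinements need no code change.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Literal

import pandas as pd

from .cohort import CohortError, DQHaplotype, HLAAllele, Individual, Locus

__all__ = [
    "DQDimer",
    "SerotypeTable",
    "SerotypeProfile",
    "enumerate_dimers",
    "assign_serotypes",
    "label_haplotype",
    "profile_individual",
    "combination_key",
    "default_serotype_table",
]

CombinationMode = Literal["haplotype_pair", "serotype_set"]


@dataclass(frozen=True, order=True)
class DQDimer:
    """One alpha/beta heterodimer; cis if both chains share a chromosome."""

    alpha: HLAAllele
    beta: HLAAllele
    configuration: str = "cis"  # "cis" or "trans"

    def __post_init__(self) -> None:
        if self.alpha.locus is not Locus.DQA1 or self.beta.locus is not Locus.DQB1:
            raise CohortError("dimer chains must be (DQA1 alpha, DQB1 beta)")
        if self.configuration not in ("cis", "trans"):
            raise CohortError(f"bad dimer configuration {self.configuration!r}")

    @property
    def allele_pair(self) -> tuple[str, str]:
        return (self.alpha.name, self.beta.name)


class SerotypeTableError(ValueError):
    """Ambiguous or malformed serotype table."""


@dataclass
class SerotypeTable:
    """Ordered (alpha pattern, beta pattern) -> serotype label map.

    Patterns are either an exact two-field allele name ("05:01") or a bare
    allele-group field ("03", matching 03:01, 03:02, ...). Entries whose
    patterns are both exact take precedence over group-pattern entries;
    within each tier the first matching entry wins. Unmatched dimers get
    ``default_label``.
    """

    entries: list[tuple[str, str, str]]
    default_label: str = "other"

    def __post_init__(self) -> None:
        exact: dict[tuple[str, str], str] = {}
        for alpha_pat, beta_pat, label in self.entries:
            for pat in (alpha_pat, beta_pat):
                if not pat or any(ch.isspace() for ch in pat):
                    raise SerotypeTableError(f"malformed pattern {pat!r}")
            if ":" in alpha_pat and ":" in beta_pat:
                key = (alpha_pat, beta_pat)
                if key in exact and exact[key] != label:
                    raise SerotypeTableError(
                        f"conflicting labels for dimer {key}: "
                        f"{exact[key]!r} vs {label!r}"
                    )
                exact[key] = label
        self._exact = exact

    def label_pair(self, alpha: HLAAllele, beta: HLAAllele) -> str:
        hit = self._exact.get((alpha.name, beta.name))
        if hit is not None:
            return hit
        for alpha_pat, beta_pat, label in self.entries:
            if _matches(alpha_pat, alpha) and _matches(beta_pat, beta):
                return label
        return self.default_label

    @property
    def labels(self) -> list[str]:
        seen: list[str] = []
        for _, _, label in self.entries:
            if label not in seen:
                seen.append(label)
        return seen


def _matches(pattern: str, allele: HLAAllele) -> bool:
    if ":" in pattern:
        return allele.name == pattern
    return allele.group_field == pattern


def default_serotype_table() -> SerotypeTable:
    """Load the shipped serotype table (DQ2.5, DQ2.2, DQ7.5, DQ6.2, DQ8.1)."""
    with resources.files("dqrisk.data").joinpath("serotype_table.tsv").open() as fh:
        return load_serotype_table(fh)


def load_serotype_table(source, default_label: str = "other") -> SerotypeTable:
    """Load a serotype table from a TSV with columns alpha_pattern, beta_pattern, label."""
    df = pd.read_csv(source, sep="\t", dtype=str)
    required = {"alpha_pattern", "beta_pattern", "label"}
    if not required.issubset(df.columns):
        raise SerotypeTableError(
            f"serotype table needs columns {sorted(required)}, got {list(df.columns)}"
        )
    entries = [
        (r.alpha_pattern, r.beta_pattern, r.label)
        for r in df.itertuples(index=False)
    ]
    return SerotypeTable(entries=entries, default_label=default_label)


# ---------------------------------------------------------------------------
# Dimer enumeration
# ---------------------------------------------------------------------------


def enumerate_dimers(hap1: DQHaplotype, hap2: DQHaplotype) -> set[DQDimer]:
    """All distinct alpha x beta heterodimers from two haplotypes.

    Returns the full cross product of the (up to two) distinct DQA1 alleles
    with the (up to two) distinct DQB1 alleles, each tagged cis when some
    input haplotype carries exactly that pair and trans otherwise; when a
    cis and a trans pairing give the same allele pair the dimer is kept
    once, flagged cis (the proteins are indistinguishable). Set size is
    always distinct-alpha-count x distinct-beta-count, i.e. 1, 2 or 4.
    """
    haps = (hap1, hap2)
    cis_pairs = {(h.dqa1, h.dqb1) for h in haps}
    out: set[DQDimer] = set()
    for alpha in {hap1.dqa1, hap2.dqa1}:
        for beta in {hap1.dqb1, hap2.dqb1}:
            config = "cis" if (alpha, beta) in cis_pairs else "trans"
            out.add(DQDimer(alpha=alpha, beta=beta, configuration=config))
    return out


def assign_serotypes(dimers: Iterable[DQDimer], table: SerotypeTable) -> set[str]:
    """Map each dimer to exactly one serotype label; return the label set."""
    return {table.label_pair(d.alpha, d.beta) for d in dimers}


def label_haplotype(hap: DQHaplotype, table: SerotypeTable) -> str:
    """Serotype label of a haplotype's own cis (dqa1, dqb1) pair."""
    return table.label_pair(hap.dqa1, hap.dqb1)


@dataclass(frozen=True)
class SerotypeProfile:
    """Per-individual serotype summary: dimers, labels, and haplotype labels."""

    individual_id: str
    dimers: frozenset[DQDimer]
    serotypes: frozenset[str]
    haplotype_labels: tuple[str, str]


def profile_individual(ind: Individual, table: SerotypeTable) -> SerotypeProfile:
    dimers = frozenset(enumerate_dimers(ind.hap1, ind.hap2))
    return SerotypeProfile(
        individual_id=ind.id,
        dimers=dimers,
        serotypes=frozenset(assign_serotypes(dimers, table)),
        haplotype_labels=(
            label_haplotype(ind.hap1, table),
            label_haplotype(ind.hap2, table),
        ),
    )


def combination_key(
    profile: SerotypeProfile, mode: CombinationMode = "haplotype_pair"
) -> str:
    """Deterministic label of an individual's HLA-DQ combination.

    ``haplotype_pair``: the unordered pair of cis haplotype labels joined
    with "/" (e.g. "DQ2.5/DQ8.1"), invariant under swapping the two
    haplotypes. ``serotype_set``: the sorted set of all serotypes the
    individual's dimers realize, joined with "+".
    """
    if mode == "haplotype_pair":
        return "/".join(sorted(profile.haplotype_labels))
    if mode == "serotype_set":
        return "+".join(sorted(profile.serotypes))
    raise ValueError(f"unknown combination mode {mode!r}")
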