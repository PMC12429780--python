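"""Domain types, file I/O and validation for case-control HLA-DQ / PLA2R1 cohorts.

A cohort is a flat table of individuals, each carrying a group label
(pMN / sMN / control), two resolved HLA-DQ haplotypes (a linked DQA1 +
DQB1 allele pair per chromosome), an rs4664308 genotype for the PLA2R1
locus, and optional PLA2R1 immunostaining / anti-PLA2R serology results.

Allele names are normalized to two-field, colon-separated protein-level
resolution ("05:01"); serotype assignment never needs synonymous or
noncoding fields, so deeper fields are truncated.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

__all__ = [
    "Locus",
    "Group",
    "Phenotype",
    "HLAAllele",
    "DQHaplotype",
    "PLA2R1Genotype",
    "Individual",
    "Cohort",
    "CohortError",
    "Dialect",
    "normalize_allele_name",
    "read_cohort",
    "write_cohort",
]


class CohortError(ValueError):
    """Invalid cohort data (bad allele string, genotype, duplicate id ...)."""


class Locus(str, enum.Enum):
    DQA1 = "DQA1"
    DQB1 = "DQB1"


class Group(str, enum.Enum):
    """Case-control group label: primary MN, secondary MN, or control."""

    PMN = "pMN"
    SMN = "sMN"
    CONTROL = "control"


class Phenotype(str, enum.Enum):
    """Result of a PLA2R1 immunostaining or anti-PLA2R serology test."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    NOT_DONE = "not_done"


_GENOTYPES = ("AA", "AG", "GG")
_RISK_DOSE = {"AA": 2, "AG": 1, "GG": 0}


@dataclass(frozen=True, order=True)
class HLAAllele:
    """A DQA1 or DQB1 allele at two-field (protein) resolution."""

    locus: Locus
    name: str

    def __post_init__(self) -> None:
        if not isinstance(self.locus, Locus):
            object.__setattr__(self, "locus", Locus(self.locus))
        if not re.fullmatch(r"\d{2,4}:\d{2,4}", self.name):
            raise CohortError(
                f"allele name {self.name!r} is not two-field colon form"
            )

    @property
    def group_field(self) -> str:
        """First (allele-group) field, e.g. '03' for 03:01."""
        return self.name.split(":")[0]

    def __str__(self) -> str:
        return f"{self.locus.value}*{self.name}"


@dataclass(frozen=True, order=True)
class DQHaplotype:
    """One chromosome's linked DQA1 + DQB1 allele pair."""

    dqa1: HLAAllele
    dqb1: HLAAllele

    def __post_init__(self) -> None:
        if self.dqa1.locus is not Locus.DQA1:
            raise CohortError(f"haplotype alpha slot holds {self.dqa1.locus}")
        if self.dqb1.locus is not Locus.DQB1:
            raise CohortError(f"haplotype beta slot holds {self.dqb1.locus}")

    def __str__(self) -> str:
        return f"{self.dqa1}~{self.dqb1}"


@dataclass(frozen=True)
class PLA2R1Genotype:
    """rs4664308 genotype; A is the risk allele (dose 2 / 1 / 0)."""

    value: str

    def __post_init__(self) -> None:
        v = self.value.upper()
        if v not in _GENOTYPES:
            raise CohortError(
                f"invalid rs4664308 genotype {self.value!r}; "
                f"expected one of {_GENOTYPES} (canonical order, AG not GA)"
            )
        object.__setattr__(self, "value", v)

    @property
    def risk_dose(self) -> int:
        return _RISK_DOSE[self.value]

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class Individual:
    id: str
    group: Group
    hap1: DQHaplotype
    hap2: DQHaplotype
    pla2r1: PLA2R1Genotype
    staining: Phenotype = Phenotype.NOT_DONE
    serology: Phenotype = Phenotype.NOT_DONE
    ethnicity: Optional[str] = None  # passthrough metadata, never computed on

    def __post_init__(self) -> None:
        if not isinstance(self.group, Group):
            object.__setattr__(self, "group", Group(self.group))
        for f in ("staining", "serology"):
            v = getattr(self, f)
            if not isinstance(v, Phenotype):
                object.__setattr__(self, f, Phenotype(v))


@dataclass
class Cohort:
    """An ordered collection of individuals with unique ids."""

    individuals: list[Individual] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for ind in self.individuals:
            if ind.id in seen:
                raise CohortError(f"duplicate individual id {ind.id!r}")
            seen.add(ind.id)

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)

    def __eq__(self, other) -> bool:
        return isinstance(other, Cohort) and self.individuals == other.individuals

    def by_group(self, group: Group | str) -> list[Individual]:
        group = Group(group)
        return [ind for ind in self.individuals if ind.group is group]

    def group_sizes(self) -> dict[str, int]:
        sizes = {g.value: 0 for g in Group}
        for ind in self.individuals:
            sizes[ind.group.value] += 1
        return sizes


# ---------------------------------------------------------------------------
# Allele-name normalization
# ---------------------------------------------------------------------------

_ALLELE_RE = re.compile(
    r"(?:HLA-)?(?P<locus>DQA1|DQB1)\s*\*?\s*(?P<fields>\d+(?::\d+)*)\s*$"
)


def normalize_allele_name(raw: str) -> HLAAllele:
    """Parse an HLA-DQ allele string into a two-field normalized allele.

    Accepts both legacy 4-/6-/8-digit names (``DQA1*0501``) and
    colon-delimited names (``DQA1*05:01``, ``DQB1*03:02:01``); fields past
    the second are truncated. Idempotent on already-normalized input.

    Raises
    ------
    CohortError
        If the string lacks a DQA1/DQB1 locus token, has fewer than four
        digits in legacy form, or is otherwise unparseable.
    """
    m = _ALLELE_RE.match(raw.strip())
    if m is None:
        raise CohortError(f"unparseable HLA allele string: {raw!r}")
    locus = Locus(m.group("locus"))
    fields_str = m.group("fields")
    if ":" in fields_str:
        fields = fields_str.split(":")
    else:
        # legacy concatenated-digit form: split into 2-digit fields
        if len(fields_str) < 4 or len(fields_str) % 2 != 0:
            raise CohortError(
                f"legacy allele designation needs an even number of at least "
                f"4 digits: {raw!r}"
            )
        fields = [fields_str[i : i + 2] for i in range(0, len(fields_str), 2)]
    first, second = fields[0], fields[1] if len(fields) > 1 else None
    if second is None:
        raise CohortError(f"allele designation has a single field: {raw!r}")
    name = f"{int(first):02d}:{int(second):02d}"
    return HLAAllele(locus=locus, name=name)


# ---------------------------------------------------------------------------
# Cohort TSV I/O
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Dialect:
    """Cohort file dialect: tab-separated, UTF-8, '.' for missing optionals."""

    delimiter: str = "\t"
    missing: str = "."
    group_labels: tuple[str, ...] = tuple(g.value for g in Group)


DEFAULT_DIALECT = Dialect()

_REQUIRED_COLUMNS = (
    "id",
    "group",
    "dqa1_1",
    "dqb1_1",
    "dqa1_2",
    "dqb1_2",
    "rs4664308",
)
_OPTIONAL_COLUMNS = ("staining", "serology", "ethnicity")


def read_cohort(path: str | Path, dialect: Dialect = DEFAULT_DIALECT) -> Cohort:
    """Read a cohort from a delimited text file with a header row.

    Required columns: id, group, dqa1_1, dqb1_1, dqa1_2, dqb1_2, rs4664308.
    Optional: staining, serology (positive/negative/not_done), ethnicity.
    Allele names are normalized; row order is preserved. Errors name the
    offending 1-based data row.
    """
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    missing_cols = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortError(f"missing required column(s): {', '.join(missing_cols)}")

    individuals: list[Individual] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        rec = row._asdict()
        try:
            group = Group(rec["group"])
        except ValueError:
            raise CohortError(
                f"row {row_no}: unknown group label {rec['group']!r}"
            ) from None
        try:
            hap1 = DQHaplotype(
                normalize_allele_name(_with_locus(rec["dqa1_1"], "DQA1")),
                normalize_allele_name(_with_locus(rec["dqb1_1"], "DQB1")),
            )
            hap2 = DQHaplotype(
                normalize_allele_name(_with_locus(rec["dqa1_2"], "DQA1")),
                normalize_allele_name(_with_locus(rec["dqb1_2"], "DQB1")),
            )
            genotype = PLA2R1Genotype(rec["rs4664308"])
        except CohortError as exc:
            raise CohortError(f"row {row_no}: {exc}") from None

        def _pheno(col: str) -> Phenotype:
            v = rec.get(col, dialect.missing)
            if v in ("", dialect.missing):
                return Phenotype.NOT_DONE
            try:
                return Phenotype(v)
            except ValueError:
                raise CohortError(
                    f"row {row_no}: invalid {col} value {v!r}"
                ) from None

        eth = rec.get("ethnicity", dialect.missing)
        individuals.append(
            Individual(
                id=rec["id"],
                group=group,
                hap1=hap1,
                hap2=hap2,
                pla2r1=genotype,
                staining=_pheno("staining"),
                serology=_pheno("serology"),
                ethnicity=None if eth in ("", dialect.missing) else eth,
            )
        )
    try:
        return Cohort(individuals)
    except CohortError as exc:
        raise CohortError(str(exc)) from None


def _with_locus(value: str, locus: str) -> str:
    """Allow bare allele designations ('05:01') in locus-specific columns."""
    v = value.strip()
    return v if v.upper().startswith(("DQA1", "DQB1", "HLA-")) else f"{locus}*{v}"


def cohort_to_frame(cohort: Cohort, dialect: Dialect = DEFAULT_DIALECT) -> pd.DataFrame:
    rows = []
    for ind in cohort:
        rows.append(
            {
                "id": ind.id,
                "group": ind.group.value,
                "dqa1_1": str(ind.hap1.dqa1),
                "dqb1_1": str(ind.hap1.dqb1),
                "dqa1_2": str(ind.hap2.dqa1),
                "dqb1_2": str(ind.hap2.dqb1),
                "rs4664308": ind.pla2r1.value,
                "staining": ind.staining.value,
                "serology": ind.serology.value,
                "ethnicity": ind.ethnicity if ind.ethnicity else dialect.missing,
            }
        )
    return pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS) + list(_OPTIONAL_COLUMNS))


def write_cohort(
    cohort: Cohort, path: str | Path, dialect: Dialect = DEFAULT_DIALECT
) -> None:
    """Write a cohort in the same TSV dialect :func:`read_cohort` accepts.

    ``read_cohort(write_cohort(c)) == c`` for any valid cohort.
    """
    df = cohort_to_frame(cohort, dialect)
    df.to_csv(path, sep=dialect.delimiter, index=False, encoding="utf-8")
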