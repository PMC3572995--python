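"""Reference allele libraries and cohort tables for DLA class II typing.

The dog leukocyte antigen (DLA) class II region carries three tightly linked,
highly polymorphic loci — DRB1, DQA1 and DQB1 — typed from exon 2. This module
defines the on-disk formats and in-memory containers shared by the whole
pipeline: a per-locus allele reference library (FASTA, headers in the
published ``DLA-<locus>*<allele>`` nomenclature), a three-locus genotype, and
a cohort table of subjects with phenotype, diagnostic-confidence grade,
relatedness grade, age and sex.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class Locus(str, Enum):
    """The three DLA class II loci typed from exon 2."""

    DRB1 = "DRB1"
    DQA1 = "DQA1"
    DQB1 = "DQB1"


#: Published exon-2 amplicon sizes (bp). Documented defaults only: library
#: consistency is checked internally, not against these numbers, because a
#: reference library may cover a different exon-2 window.
EXPECTED_LENGTH: dict[Locus, int] = {Locus.DRB1: 303, Locus.DQA1: 345, Locus.DQB1: 300}

LOCI: tuple[Locus, ...] = (Locus.DRB1, Locus.DQA1, Locus.DQB1)

_VALID_BASES = set("ACGT")


class FormatError(ValueError):
    """Malformed input record (header, token, or row)."""


class AlignmentFrameError(ValueError):
    """Sequences at one locus do not share the exon-2 alignment frame."""


class DuplicateError(ValueError):
    """Duplicate allele name or subject id."""


@dataclass(frozen=True)
class Allele:
    """A named exon-2 allele sequence, stored in sense orientation."""

    locus: Locus
    name: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise FormatError(
                f"allele {self.locus.value}*{self.name}: ambiguous or invalid "
                f"bases {sorted(bad)} in reference sequence"
            )

    @property
    def full_name(self) -> str:
        return f"DLA-{self.locus.value}*{self.name}"


class AlleleLibrary:
    """Per-locus mapping of allele name -> :class:`Allele`.

    All alleles at one locus must have equal sequence length: the library is a
    pre-aligned exon-2 frame, so diploid superposition and exact matching are
    positional.
    """

    def __init__(self, alleles: Iterable[Allele], provenance: str = "") -> None:
        self.provenance = provenance
        self._by_locus: dict[Locus, dict[str, Allele]] = {loc: {} for loc in LOCI}
        for allele in alleles:
            table = self._by_locus[allele.locus]
            if allele.name in table:
                raise DuplicateError(f"duplicate allele {allele.full_name}")
            prior = next(iter(table.values()), None)
            if prior is not None and len(prior.sequence) != len(allele.sequence):
                raise AlignmentFrameError(
                    f"{allele.full_name}: length {len(allele.sequence)} differs "
                    f"from locus frame {len(prior.sequence)}"
                )
            table[allele.name] = allele

    def alleles(self, locus: Locus) -> list[Allele]:
        return list(self._by_locus[locus].values())

    def names(self, locus: Locus) -> list[str]:
        return list(self._by_locus[locus])

    def get(self, locus: Locus, name: str) -> Allele:
        try:
            return self._by_locus[locus][name]
        except KeyError:
            raise KeyError(f"allele DLA-{locus.value}*{name} not in library") from None

    def __contains__(self, key: tuple[Locus, str]) -> bool:
        locus, name = key
        return name in self._by_locus[locus]

    def n_alleles(self, locus: Locus) -> int:
        return len(self._by_locus[locus])

    def frame_length(self, locus: Locus) -> Optional[int]:
        table = self._by_locus[locus]
        if not table:
            return None
        return len(next(iter(table.values())).sequence)

    def __iter__(self):
        for locus in LOCI:
            yield from self._by_locus[locus].values()


def _parse_header(header: str) -> tuple[Locus, str]:
    token = header.split()[0]
    if not token.startswith("DLA-") or "*" not in token:
        raise FormatError(f"FASTA header {header!r}: expected 'DLA-<locus>*<name>'")
    locus_str, _, name = token[4:].partition("*")
    try:
        locus = Locus(locus_str)
    except ValueError:
        raise FormatError(f"FASTA header {header!r}: unknown locus {locus_str!r}") from None
    if not name:
        raise FormatError(f"FASTA header {header!r}: empty allele name")
    return locus, name


def load_allele_library(path: str | Path, provenance: str = "") -> AlleleLibrary:
    """Read a per-locus allele reference library from FASTA.

    Headers follow the published nomenclature ``DLA-<locus>*<name>``; anything
    after the first whitespace is ignored. Sequences are uppercased and U
    mapped to T before validation.
    """
    alleles = []
    for record in SeqIO.parse(str(path), "fasta"):
        locus, name = _parse_header(record.description or record.id)
        seq = str(record.seq).upper().replace("U", "T")
        alleles.append(Allele(locus=locus, name=name, sequence=seq))
    library = AlleleLibrary(alleles, provenance=provenance or str(path))
    if all(library.n_alleles(loc) == 0 for loc in LOCI):
        raise FormatError(f"{path}: no allele records found")
    return library


def write_allele_library(library: AlleleLibrary, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(a.sequence), id=a.full_name, description="") for a in library
    ]
    SeqIO.write(records, str(path), "fasta")


@dataclass(frozen=True)
class ThreeLocusGenotype:
    """Unordered allele-name pair at each of the three loci.

    A locus may be missing (``None``), representing a typing failure; such a
    dog is excluded from phasing but still contributes its typed loci to
    allele-level analyses. Pairs are stored sorted so equality is unordered.
    """

    drb1: Optional[tuple[str, str]]
    dqa1: Optional[tuple[str, str]]
    dqb1: Optional[tuple[str, str]]

    def __post_init__(self) -> None:
        for locus_field in ("drb1", "dqa1", "dqb1"):
            pair = getattr(self, locus_field)
            if pair is not None:
                object.__setattr__(self, locus_field, tuple(sorted(pair)))

    def pair(self, locus: Locus) -> Optional[tuple[str, str]]:
        return getattr(self, locus.value.lower())

    @property
    def complete(self) -> bool:
        return all(self.pair(loc) is not None for loc in LOCI)

    def heterozygosity(self) -> int:
        """Number of loci (0..3) at which the two alleles differ."""
        if not self.complete:
            raise ValueError("heterozygosity undefined for incomplete genotype")
        return sum(1 for loc in LOCI if len(set(self.pair(loc))) == 2)


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


class Status(str, Enum):
    CASE = "case"
    CONTROL = "control"


class DiagnosticGrade(str, Enum):
    """Diagnostic-confidence grading of cases.

    ``definite``: biopsy-confirmed inflammatory pathology with masticatory
    muscle myositis excluded; ``probable``: biopsy-confirmed, MMM excluded on
    clinical signs only; ``possible``: clinical signs without biopsy.
    Controls carry ``not_applicable``.
    """

    DEFINITE = "definite"
    PROBABLE = "probable"
    POSSIBLE = "possible"
    NOT_APPLICABLE = "not_applicable"


class RelatednessGrade(str, Enum):
    """Graded-control stratum: relationship to the nearest affected dog."""

    FIRST_DEGREE = "first_degree"
    SECOND_DEGREE = "second_degree"
    UNRELATED = "unrelated"
    CASE = "case"


@dataclass
class Subject:
    """One dog: phenotype, strata, genotype and (after phasing) haplotypes."""

    id: str
    status: Status
    sex: Sex = Sex.UNKNOWN
    diagnostic_grade: DiagnosticGrade = DiagnosticGrade.NOT_APPLICABLE
    relatedness_grade: RelatednessGrade = RelatednessGrade.UNRELATED
    age_years: Optional[float] = None
    genotype: Optional[ThreeLocusGenotype] = None
    # set by phasing: unordered pair of Haplotype (phasing.Haplotype)
    haplotypes: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.status is Status.CASE:
            if self.diagnostic_grade is DiagnosticGrade.NOT_APPLICABLE:
                raise FormatError(f"subject {self.id}: case needs a diagnostic grade")
            if self.relatedness_grade is not RelatednessGrade.CASE:
                raise FormatError(
                    f"subject {self.id}: cases carry relatedness grade 'case'"
                )
        else:
            if self.diagnostic_grade is not DiagnosticGrade.NOT_APPLICABLE:
                raise FormatError(
                    f"subject {self.id}: controls carry grade 'not_applicable'"
                )
        if self.age_years is not None and self.age_years < 0:
            raise FormatError(f"subject {self.id}: negative age")


COHORT_COLUMNS = ("id", "status", "sex", "diagnostic_grade", "relatedness_grade", "age_years")

GENOTYPE_COLUMNS = (
    "id",
    "DRB1_1", "DRB1_2",
    "DQA1_1", "DQA1_2",
    "DQB1_1", "DQB1_2",
)


@dataclass
class CohortLoadResult:
    subjects: list[Subject]
    rejected: list[tuple[int, str]] = field(default_factory=list)  # (row, reason)

    @property
    def n_input_rows(self) -> int:
        return len(self.subjects) + len(self.rejected)


def _sniff_delimiter(path: Path) -> str:
    first = path.read_text().splitlines()[0]
    return "\t" if "\t" in first else ","


def load_cohort(path: str | Path, strict: bool = False) -> CohortLoadResult:
    """Read a cohort table (CSV, tab accepted) into Subjects.

    Required columns: ``id``, ``status``. Every input row either yields a
    Subject or is reported in ``rejected`` with its row number and reason —
    rows are never silently dropped. With ``strict=True`` the first bad row
    raises instead.
    """
    path = Path(path)
    delim = _sniff_delimiter(path)
    subjects: list[Subject] = []
    rejected: list[tuple[int, str]] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None or not {"id", "status"} <= set(reader.fieldnames):
            raise FormatError(f"{path}: cohort table needs 'id' and 'status' columns")
        for i, row in enumerate(reader, start=2):
            try:
                subjects.append(_subject_from_row(row, seen))
            except (FormatError, DuplicateError, ValueError) as exc:
                if strict:
                    raise FormatError(f"{path} row {i}: {exc}") from exc
                rejected.append((i, str(exc)))
    return CohortLoadResult(subjects=subjects, rejected=rejected)


def _subject_from_row(row: Mapping[str, str], seen: set[str]) -> Subject:
    sid = (row.get("id") or "").strip()
    if not sid:
        raise FormatError("empty id")
    if sid in seen:
        raise DuplicateError(f"duplicate id {sid!r}")
    status = Status((row.get("status") or "").strip().lower())
    def enum_field(name, enum, default):
        raw = (row.get(name) or "").strip().lower()
        if not raw:
            return default
        try:
            return enum(raw)
        except ValueError:
            raise FormatError(f"unknown {name} token {raw!r}") from None
    sex = enum_field("sex", Sex, Sex.UNKNOWN)
    grade_default = (
        DiagnosticGrade.NOT_APPLICABLE if status is Status.CONTROL else DiagnosticGrade.POSSIBLE
    )
    grade = enum_field("diagnostic_grade", DiagnosticGrade, grade_default)
    rel_default = (
        RelatednessGrade.CASE if status is Status.CASE else RelatednessGrade.UNRELATED
    )
    rel = enum_field("relatedness_grade", RelatednessGrade, rel_default)
    age_raw = (row.get("age_years") or "").strip()
    age = float(age_raw) if age_raw else None
    subject = Subject(
        id=sid, status=status, sex=sex, diagnostic_grade=grade,
        relatedness_grade=rel, age_years=age,
    )
    seen.add(sid)
    return subject


def write_cohort(subjects: Iterable[Subject], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for s in subjects:
            writer.writerow([
                s.id, s.status.value, s.sex.value, s.diagnostic_grade.value,
                s.relatedness_grade.value,
                "" if s.age_years is None else f"{s.age_years:g}",
            ])


def write_genotypes(subjects: Iterable[Subject], path: str | Path) -> None:
    """Wide genotype table: two allele-name columns per locus, blank if untyped."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(GENOTYPE_COLUMNS)
        for s in subjects:
            row = [s.id]
            g = s.genotype
            for locus in LOCI:
                pair = None if g is None else g.pair(locus)
                row.extend(["", ""] if pair is None else list(pair))
            writer.writerow(row)


def load_genotypes(path: str | Path) -> dict[str, ThreeLocusGenotype]:
    path = Path(path)
    delim = _sniff_delimiter(path)
    out: dict[str, ThreeLocusGenotype] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        missing = set(GENOTYPE_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise FormatError(f"{path}: genotype table missing columns {sorted(missing)}")
        for row in reader:
            sid = row["id"].strip()
            if sid in out:
                raise DuplicateError(f"{path}: duplicate id {sid!r}")
            pairs = {}
            for locus in LOCI:
                a1 = row[f"{locus.value}_1"].strip()
                a2 = row[f"{locus.value}_2"].strip()
                pairs[locus.value.lower()] = (a1, a2) if a1 and a2 else None
            out[sid] = ThreeLocusGenotype(**pairs)
    return out


def attach_genotypes(
    subjects: Iterable[Subject], genotypes: Mapping[str, ThreeLocusGenotype]
) -> list[Subject]:
    return [replace(s, genotype=genotypes.get(s.id, s.genotype)) for s in subjects]
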