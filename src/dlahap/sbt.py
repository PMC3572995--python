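"""Sequence-based typing: resolve an unordered allele pair from one ambiguous read.

Exon-2 amplicons are Sanger-sequenced in a single direction (reverse for DRB1
and DQA1, forward for DQB1), so each dog yields one consensus string per locus
in which heterozygous positions appear as two-base IUPAC ambiguity codes. The
diploid consensus is the position-wise *superposition* of the two allele
sequences; typing inverts this by exact matching against a reference library:
the candidate set is every unordered allele pair whose superposition equals
the read. No mismatch tolerance is applied — the consensus is assumed
base-called and manually curated upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reference import Allele, AlleleLibrary, FormatError, Locus

#: IUPAC code -> set of bases it covers (e.g. R -> {A, G}).
IUPAC_TO_BASES: dict[str, frozenset[str]] = {
    code: frozenset(bases) for code, bases in ambiguous_dna_values.items()
}
#: frozenset of 1 or 2 bases -> the IUPAC code for their union.
BASES_TO_IUPAC: dict[frozenset[str], str] = {
    bases: code for code, bases in IUPAC_TO_BASES.items() if len(bases) <= 2
}

_TWO_BASE_OR_LESS = {c for c, b in IUPAC_TO_BASES.items() if len(b) <= 2}

#: Native Sanger read orientation per locus.
NATIVE_ORIENTATION: dict[Locus, str] = {
    Locus.DRB1: "antisense",
    Locus.DQA1: "antisense",
    Locus.DQB1: "sense",
}


def superpose(seq_a: str, seq_b: str) -> str:
    """Position-wise diploid consensus of two unambiguous sequences.

    Identical bases pass through; differing bases map to the two-base IUPAC
    code (A/G -> R, C/T -> Y, ...). Commutative by construction.
    """
    if len(seq_a) != len(seq_b):
        raise FormatError(
            f"superpose: length mismatch {len(seq_a)} vs {len(seq_b)}"
        )
    out = []
    for x, y in zip(seq_a, seq_b):
        try:
            out.append(BASES_TO_IUPAC[frozenset((x, y))])
        except KeyError:
            raise FormatError(f"superpose: invalid bases {x!r}/{y!r}") from None
    return "".join(out)


@dataclass(frozen=True)
class AmbiguousRead:
    """One single-direction consensus read for one sample at one locus."""

    sample: str
    locus: Locus
    sequence: str
    orientation: str = "sense"  # sense | antisense

    def __post_init__(self) -> None:
        if self.orientation not in ("sense", "antisense"):
            raise FormatError(f"read {self.sample}: bad orientation {self.orientation!r}")
        bad = set(self.sequence.upper()) - set(IUPAC_TO_BASES)
        if bad:
            raise FormatError(f"read {self.sample}/{self.locus.value}: invalid IUPAC {sorted(bad)}")
        object.__setattr__(self, "sequence", self.sequence.upper())


def normalize_orientation(read: AmbiguousRead) -> AmbiguousRead:
    """Reverse-complement antisense reads into sense orientation (idempotent).

    IUPAC codes complement pairwise (R<->Y, K<->M, S and W self-complementary),
    which ``Bio.Seq`` handles.
    """
    if read.orientation == "sense":
        return read
    rc = str(Seq(read.sequence).reverse_complement())
    return replace(read, sequence=rc, orientation="sense")


class CallStatus(str, Enum):
    RESOLVED = "resolved"
    AMBIGUOUS = "ambiguous"
    NO_MATCH = "no_match"            # novel allele or sequencing error
    UNRESOLVABLE = "unresolvable"    # read contains 3/4-base codes (e.g. N)
    FRAME_MISMATCH = "frame_mismatch"


@dataclass
class AllelePairCall:
    """Candidate unordered allele pairs consistent with one read."""

    sample: str
    locus: Locus
    candidates: list[tuple[str, str]] = field(default_factory=list)
    status: CallStatus = CallStatus.NO_MATCH

    @property
    def resolved(self) -> Optional[tuple[str, str]]:
        return self.candidates[0] if self.status is CallStatus.RESOLVED else None


def resolve_allele_pair(
    read: AmbiguousRead,
    library: AlleleLibrary,
    prior_frequencies: Optional[dict[str, float]] = None,
) -> AllelePairCall:
    """Type one read: every unordered pair (a, b), a = b allowed, with
    ``superpose(a, b) == read`` is a candidate.

    A diploid superposition only ever produces 1- or 2-base codes, so reads
    containing 3/4-base codes (N, V, ...) are reported ``unresolvable`` rather
    than matched. With several consistent pairs the call is left ambiguous
    unless ``prior_frequencies`` is given, in which case the pair with the
    highest product of priors is promoted to resolved (ties stay ambiguous).
    """
    read = normalize_orientation(read)
    call = AllelePairCall(sample=read.sample, locus=read.locus)
    if set(read.sequence) - _TWO_BASE_OR_LESS:
        call.status = CallStatus.UNRESOLVABLE
        return call
    frame = library.frame_length(read.locus)
    if frame is None or frame != len(read.sequence):
        call.status = CallStatus.FRAME_MISMATCH
        return call

    # An allele can participate only if compatible with the read everywhere.
    compatible: list[Allele] = [
        a for a in library.alleles(read.locus)
        if all(base in IUPAC_TO_BASES[code] for base, code in zip(a.sequence, read.sequence))
    ]
    for i, a in enumerate(compatible):
        for b in compatible[i:]:
            if superpose(a.sequence, b.sequence) == read.sequence:
                call.candidates.append(tuple(sorted((a.name, b.name))))
    call.candidates.sort()

    if not call.candidates:
        call.status = CallStatus.NO_MATCH
    elif len(call.candidates) == 1:
        call.status = CallStatus.RESOLVED
    else:
        call.status = CallStatus.AMBIGUOUS
        if prior_frequencies is not None:
            scored = sorted(
                call.candidates,
                key=lambda p: prior_frequencies.get(p[0], 0.0) * prior_frequencies.get(p[1], 0.0),
                reverse=True,
            )
            s0 = prior_frequencies.get(scored[0][0], 0.0) * prior_frequencies.get(scored[0][1], 0.0)
            s1 = prior_frequencies.get(scored[1][0], 0.0) * prior_frequencies.get(scored[1][1], 0.0)
            if s0 > s1:
                call.candidates = [scored[0]] + scored[1:]
                call.status = CallStatus.RESOLVED
    return call


def type_reads(
    reads: Iterable[AmbiguousRead],
    library: AlleleLibrary,
    prior_frequencies: Optional[dict[str, float]] = None,
) -> list[AllelePairCall]:
    return [resolve_allele_pair(r, library, prior_frequencies) for r in reads]


# --- read FASTA dialect: header "sample|locus|orientation" ------------------

def load_reads(path: str | Path) -> list[AmbiguousRead]:
    reads = []
    for record in SeqIO.parse(str(path), "fasta"):
        parts = (record.description or record.id).split()[0].split("|")
        if len(parts) != 3:
            raise FormatError(f"read header {record.id!r}: expected 'sample|locus|orientation'")
        sample, locus_str, orientation = parts
        try:
            locus = Locus(locus_str)
        except ValueError:
            raise FormatError(f"read header {record.id!r}: unknown locus {locus_str!r}") from None
        reads.append(AmbiguousRead(sample=sample, locus=locus,
                                   sequence=str(record.seq), orientation=orientation))
    return reads


def write_reads(reads: Iterable[AmbiguousRead], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(r.sequence), id=f"{r.sample}|{r.locus.value}|{r.orientation}",
                  description="")
        for r in reads
    ]
    SeqIO.write(records, str(path), "fasta")


def write_calls(calls: Iterable[AllelePairCall], path: str | Path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample", "locus", "allele1", "allele2", "n_candidates", "status"])
        for c in calls:
            a1, a2 = c.resolved if c.resolved else ("", "")
            writer.writerow([c.sample, c.locus.value, a1, a2, len(c.candidates), c.status.value])
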