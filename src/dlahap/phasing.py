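"""Homozygote-seeded three-locus haplotype phasing (Clark-style).

Within one breed the three DLA class II loci form a single tightly linked
block with limited haplotype diversity, which makes a conservative parsimony
procedure effective:

1. Dogs homozygous at all three loci (h = 0) each carry two copies of one
   unambiguous haplotype; these seed the pool.
2. Dogs heterozygous at exactly one locus (h = 1) phase deterministically —
   the two alleles at the heterozygous locus each combine with the homozygous
   background — confirming and extending the pool.
3. Remaining dogs (h >= 2) are examined against the pool: among the
   2^(h-1) haplotype pairs consistent with the genotype, a dog is phased when
   exactly one pair has both members already established. A parsimony
   fallback admits at most one novel haplotype per dog (the partner of a
   pooled haplotype) when no fully pooled pair exists.

Processing is by heterozygosity stratum with the h >= 2 pass iterated to a
fixed point; within a pass every dog is evaluated against the pool frozen at
the start of the pass, so results are independent of subject order.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional

from .reference import LOCI, Locus, ThreeLocusGenotype


class Haplotype(NamedTuple):
    """Ordered allele-name triple on one chromosome: (DRB1, DQA1, DQB1)."""

    drb1: str
    dqa1: str
    dqb1: str

    @property
    def name(self) -> str:
        return f"{self.drb1}-{self.dqa1}-{self.dqb1}"

    @classmethod
    def from_name(cls, name: str) -> "Haplotype":
        parts = name.split("-")
        if len(parts) != 3 or not all(parts):
            raise ValueError(f"haplotype name {name!r}: expected 'drb1-dqa1-dqb1'")
        return cls(*parts)


class Provenance(str, Enum):
    SEED_FULL_HOMOZYGOTE = "seed_full_homozygote"
    SEED_PARTIAL_HOMOZYGOTE = "seed_partial_homozygote"
    INFERRED = "inferred"


class PhaseStatus(str, Enum):
    PHASED = "phased"
    AMBIGUOUS = "ambiguous"
    UNRESOLVED = "unresolved"
    EXCLUDED = "excluded"  # missing locus


HaplotypePair = tuple[Haplotype, Haplotype]


def _sorted_pair(a: Haplotype, b: Haplotype) -> HaplotypePair:
    return (a, b) if a <= b else (b, a)


@dataclass
class SubjectPhase:
    status: PhaseStatus
    pair: Optional[HaplotypePair] = None
    candidate_pairs: list[HaplotypePair] = field(default_factory=list)
    provenance: Optional[Provenance] = None


@dataclass
class PhasingResult:
    assignments: dict[str, SubjectPhase]
    pool: dict[Haplotype, Provenance]

    def phased_ids(self) -> set[str]:
        return {k for k, v in self.assignments.items() if v.status is PhaseStatus.PHASED}

    def pool_counts(self) -> dict[Haplotype, int]:
        counts: dict[Haplotype, int] = {h: 0 for h in self.pool}
        for sp in self.assignments.values():
            if sp.pair is not None:
                for h in sp.pair:
                    counts[h] = counts.get(h, 0) + 1
        return counts


def heterozygosity(g: ThreeLocusGenotype) -> int:
    return g.heterozygosity()


def consistent_pairs(g: ThreeLocusGenotype) -> list[HaplotypePair]:
    """All unordered haplotype pairs whose per-locus allele multisets equal the
    genotype's pairs: 2^(h-1) pairs for heterozygosity h >= 1, one for h = 0."""
    if not g.complete:
        raise ValueError("cannot enumerate pairs of an incomplete genotype")
    per_locus = [g.pair(loc) for loc in LOCI]
    seen: set[HaplotypePair] = set()
    for picks in product((0, 1), repeat=3):
        hap_a = Haplotype(*(pair[pick] for pair, pick in zip(per_locus, picks)))
        hap_b = Haplotype(*(pair[1 - pick] for pair, pick in zip(per_locus, picks)))
        seen.add(_sorted_pair(hap_a, hap_b))
    return sorted(seen)


def pair_matches_genotype(pair: HaplotypePair, g: ThreeLocusGenotype) -> bool:
    """True iff the pair's per-locus allele multiset reconstructs the genotype."""
    a, b = pair
    for locus, x, y in zip(LOCI, a, b):
        if tuple(sorted((x, y))) != g.pair(locus):
            return False
    return True


def seed_from_homozygotes(
    genotypes: Mapping[str, ThreeLocusGenotype],
) -> tuple[dict[Haplotype, Provenance], dict[str, SubjectPhase]]:
    """Step 1: fully homozygous dogs each contribute one haplotype, twice."""
    pool: dict[Haplotype, Provenance] = {}
    assignments: dict[str, SubjectPhase] = {}
    for sid in sorted(genotypes):
        g = genotypes[sid]
        if g.heterozygosity() != 0:
            continue
        hap = Haplotype(*(g.pair(loc)[0] for loc in LOCI))
        pool.setdefault(hap, Provenance.SEED_FULL_HOMOZYGOTE)
        assignments[sid] = SubjectPhase(
            status=PhaseStatus.PHASED, pair=(hap, hap),
            provenance=Provenance.SEED_FULL_HOMOZYGOTE,
        )
    return pool, assignments


def extend_with_partial_homozygotes(
    genotypes: Mapping[str, ThreeLocusGenotype],
    pool: dict[Haplotype, Provenance],
    assignments: dict[str, SubjectPhase],
) -> None:
    """Step 2: single-locus heterozygotes phase deterministically; their two
    implied haplotypes confirm or extend the pool."""
    for sid in sorted(genotypes):
        g = genotypes[sid]
        if g.heterozygosity() != 1 or sid in assignments:
            continue
        pairs = consistent_pairs(g)
        assert len(pairs) == 1
        pair = pairs[0]
        for hap in pair:
            pool.setdefault(hap, Provenance.SEED_PARTIAL_HOMOZYGOTE)
        assignments[sid] = SubjectPhase(
            status=PhaseStatus.PHASED, pair=pair,
            provenance=Provenance.SEED_PARTIAL_HOMOZYGOTE,
        )


def resolve_remaining(
    genotypes: Mapping[str, ThreeLocusGenotype],
    pool: dict[Haplotype, Provenance],
    assignments: dict[str, SubjectPhase],
    rank_ambiguous: bool = False,
) -> None:
    """Step 3: iterate pool-consistent inference over h >= 2 dogs to a fixed
    point, then apply the single-novel-haplotype parsimony fallback, also to a
    fixed point. Each pass evaluates all unassigned dogs against the pool
    frozen at the pass start (order independence)."""

    def pass_once(allow_novel: bool) -> bool:
        frozen = set(pool)
        new_assignments: dict[str, SubjectPhase] = {}
        novel: dict[Haplotype, Provenance] = {}
        for sid in sorted(genotypes):
            if sid in assignments:
                continue
            pairs = consistent_pairs(genotypes[sid])
            pooled = [p for p in pairs if p[0] in frozen and p[1] in frozen]
            if len(pooled) == 1:
                new_assignments[sid] = SubjectPhase(
                    status=PhaseStatus.PHASED, pair=pooled[0],
                    provenance=Provenance.INFERRED,
                )
            elif not pooled and allow_novel:
                half = [p for p in pairs if (p[0] in frozen) != (p[1] in frozen)]
                if len(half) == 1:
                    pair = half[0]
                    new_hap = pair[1] if pair[0] in frozen else pair[0]
                    novel[new_hap] = Provenance.INFERRED
                    new_assignments[sid] = SubjectPhase(
                        status=PhaseStatus.PHASED, pair=pair,
                        provenance=Provenance.INFERRED,
                    )
        assignments.update(new_assignments)
        for hap, prov in novel.items():
            pool.setdefault(hap, prov)
        return bool(new_assignments)

    # Pool-only inference first; novel haplotypes only once it stalls, then
    # pool-only again, until neither makes progress.
    progress = True
    while progress:
        while pass_once(allow_novel=False):
            pass
        progress = pass_once(allow_novel=True)

    # Classify whatever is left.
    for sid in sorted(genotypes):
        if sid in assignments:
            continue
        pairs = consistent_pairs(genotypes[sid])
        pooled = [p for p in pairs if p[0] in pool and p[1] in pool]
        if len(pooled) > 1:
            if rank_ambiguous:
                counts = {h: 0 for h in pool}
                for sp in assignments.values():
                    if sp.pair:
                        for h in sp.pair:
                            counts[h] = counts.get(h, 0) + 1
                pooled.sort(key=lambda p: -(counts.get(p[0], 0) * counts.get(p[1], 0)))
            assignments[sid] = SubjectPhase(
                status=PhaseStatus.AMBIGUOUS, candidate_pairs=pooled
            )
        else:
            assignments[sid] = SubjectPhase(
                status=PhaseStatus.UNRESOLVED, candidate_pairs=pairs
            )


def phase_cohort(
    genotypes: Mapping[str, ThreeLocusGenotype],
    rank_ambiguous: bool = False,
) -> PhasingResult:
    """Run the full three-step procedure over a cohort of genotypes.

    Dogs with a missing locus are excluded (status ``excluded``) — they cannot
    constrain a three-locus haplotype.
    """
    complete = {sid: g for sid, g in genotypes.items() if g.complete}
    pool, assignments = seed_from_homozygotes(complete)
    extend_with_partial_homozygotes(complete, pool, assignments)
    resolve_remaining(complete, pool, assignments, rank_ambiguous=rank_ambiguous)
    for sid, g in genotypes.items():
        if not g.complete:
            assignments[sid] = SubjectPhase(status=PhaseStatus.EXCLUDED)
    for sid, sp in assignments.items():
        if sp.pair is not None:
            assert pair_matches_genotype(sp.pair, genotypes[sid]), sid
    return PhasingResult(assignments=assignments, pool=pool)


# --- output tables ----------------------------------------------------------

def write_phasing(result: PhasingResult, subjects_path: str | Path, pool_path: str | Path) -> None:
    with open(subjects_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject", "hap1", "hap2", "status", "provenance", "n_candidates"])
        for sid in sorted(result.assignments):
            sp = result.assignments[sid]
            h1, h2 = (sp.pair[0].name, sp.pair[1].name) if sp.pair else ("", "")
            writer.writerow([
                sid, h1, h2, sp.status.value,
                sp.provenance.value if sp.provenance else "",
                len(sp.candidate_pairs) or (1 if sp.pair else 0),
            ])
    counts = result.pool_counts()
    with open(pool_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["haplotype", "count", "provenance"])
        for hap in sorted(result.pool, key=lambda h: (-counts.get(h, 0), h)):
            writer.writerow([hap.name, counts.get(hap, 0), result.pool[hap].value])


def load_phasing(path: str | Path) -> dict[str, SubjectPhase]:
    out: dict[str, SubjectPhase] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            status = PhaseStatus(row["status"])
            pair = None
            if row["hap1"] and row["hap2"]:
                pair = _sorted_pair(Haplotype.from_name(row["hap1"]),
                                    Haplotype.from_name(row["hap2"]))
            prov = Provenance(row["provenance"]) if row["provenance"] else None
            out[row["subject"]] = SubjectPhase(status=status, pair=pair, provenance=prov)
    return out


def apply_phasing(subjects: Iterable, result: PhasingResult) -> None:
    """Attach phased pairs to Subject objects in place."""
    for s in subjects:
        sp = result.assignments.get(s.id)
        s.haplotypes = sp.pair if sp is not None else None
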