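"""Bundled reference datasets: the breed-cohort count fixture and a toy library.

``reference_cohort`` reconstructs, dog by dog, a published single-breed
case-control study of canine polymyositis: 29 cases (13 definite, 4 probable,
12 possible) and 183 graded controls (93 first-degree, 44 second-degree, 46
unrelated), phased for eleven three-locus DLA haplotypes with the published
per-group chromosome counts. It exists so the statistics layer has an exact
regression anchor independent of typing and phasing — the haplotype pairs are
encoded directly.

The published tables are mutually inconsistent by one chromosome: the
per-group haplotype table implies 25 risk-haplotype chromosomes among the 46
unrelated controls, while the genotype-dose table's 24/18/4 split implies 26.
Both variants are provided; see the ``dose_variant`` argument.

``toy_library`` builds a synthetic pre-aligned allele library over short
sequences, constructed so that every unordered allele pair has a unique
diploid superposition (one-hot design), making typing exact.
"""

from __future__ import annotations

from typing import Literal

from .phasing import Haplotype
from .reference import (
    Allele,
    AlleleLibrary,
    DiagnosticGrade,
    LOCI,
    Locus,
    RelatednessGrade,
    Sex,
    Status,
    Subject,
)
from .simulate import genotype_of

# The seven common haplotypes, by decreasing all-control frequency rank.
H1 = Haplotype("02001", "00401", "01303")   # the risk haplotype
H2 = Haplotype("00601", "005011", "00701")
H3 = Haplotype("00901", "00101", "008011")
H4 = Haplotype("00801", "00301", "00401")
H5 = Haplotype("02301", "00301", "00501")
H6 = Haplotype("01501", "00601", "02301")   # putatively protective
H7 = Haplotype("04801", "00101", "008011")
# Four rare haplotypes, unnamed in the source counts; synthetic stand-in
# allele triples (chosen to keep the library at 8/7/8 distinct alleles).
R1 = Haplotype("01101", "00201", "01302")
R2 = Haplotype("02001", "00901", "00101")
R3 = Haplotype("00901", "00301", "00501")
R4 = Haplotype("00801", "00401", "01303")

RISK = H1
PROTECTIVE = H6
ALL_HAPLOTYPES = (H1, H2, H3, H4, H5, H6, H7, R1, R2, R3, R4)


def _pair_multiset(counts: dict[Haplotype, int]) -> list[tuple[Haplotype, Haplotype]]:
    """Pair chromosomes into dogs, greedily pairing the two most frequent
    distinct haplotypes (maximal heterozygosity; deterministic)."""
    counts = {h: c for h, c in counts.items() if c > 0}
    pairs = []
    while counts:
        ordered = sorted(counts, key=lambda h: (-counts[h], h))
        first = ordered[0]
        second = ordered[1] if len(ordered) > 1 else ordered[0]
        pairs.append((first, second))
        for h in {first, second}:
            counts[h] -= 2 if first == second else 1
            if counts[h] <= 0:
                del counts[h]
    return pairs


def _dogs(n_hom: int, het_partners: list[Haplotype],
          zero_counts: dict[Haplotype, int]) -> list[tuple[Haplotype, Haplotype]]:
    dogs = [(RISK, RISK)] * n_hom
    dogs += [(RISK, partner) for partner in het_partners]
    dogs += _pair_multiset(dict(zero_counts))
    return dogs


def _case_pairs() -> list[tuple[Haplotype, Haplotype]]:
    # 58 chromosomes: H1 35, H2 12, H3 5, H4 3, H5 2, H6 1
    het = [H2] * 9 + [H3] * 3 + [H4] * 2 + [H5]
    zero = [(H2, H2), (H2, H3), (H3, H4), (H5, H6)]
    return [(RISK, RISK)] * 10 + [(RISK, p) for p in het] + zero


def _first_degree_pairs() -> list[tuple[Haplotype, Haplotype]]:
    # 186 chromosomes: H1 96, H2 35, H3 19, H4 17, H5 13, H6 5, H7 1
    het = [H2] * 17 + [H3] * 9 + [H4] * 9 + [H5] * 7 + [H6] * 3 + [H7]
    zero = {H2: 18, H3: 10, H4: 8, H5: 6, H6: 2}
    return _dogs(25, het, zero)


def _second_degree_pairs() -> list[tuple[Haplotype, Haplotype]]:
    # 88 chromosomes: H1 41, H2 14, H3 7, H4 12, H5 10, H6 2, H7 2
    het = [H2] * 7 + [H3] * 3 + [H4] * 6 + [H5] * 5 + [H6] + [H7]
    zero = {H2: 7, H3: 4, H4: 6, H5: 5, H6: 1, H7: 1}
    return _dogs(9, het, zero)


def _unrelated_pairs(dose_variant: str) -> list[tuple[Haplotype, Haplotype]]:
    # 92 chromosomes: H2 23, H3 5, H4 15, H5 2, H6 9, H7 6, rare 7; risk 25
    # (haplotype-table variant) or 26 (dose-table variant).
    rare = {R1: 2, R2: 2, R3: 2, R4: 1}
    if dose_variant == "haplotype_counts":
        het = [H2] * 6 + [H3] + [H4] * 4 + [H5] + [H6] * 3 + [H7] * 2
        zero = {H2: 17, H3: 4, H4: 11, H5: 1, H6: 6, H7: 4, **rare}
    elif dose_variant == "dose_counts":
        het = [H2] * 7 + [H3] + [H4] * 4 + [H5] + [H6] * 3 + [H7] * 2
        zero = {H2: 15, H3: 4, H4: 11, H5: 1, H6: 6, H7: 4, **rare}
    else:
        raise ValueError(f"dose_variant must be 'haplotype_counts' or 'dose_counts', got {dose_variant!r}")
    return _dogs(4, het, zero)


# Onset ages crafted so homozygous cases average 3.28 y and the rest 2.83 y,
# within the reported 0.5-8 y range.
_CASE_AGES_HOM = [0.5, 1.8, 2.5, 3.0, 3.2, 3.5, 3.8, 4.0, 4.5, 6.0]
_CASE_AGES_OTHER = [0.5, 0.8, 1.2, 1.5, 1.8, 2.0, 2.2, 2.2, 2.5, 2.5,
                    2.7, 2.9, 3.0, 3.2, 3.5, 3.8, 4.0, 5.5, 8.0]


def _case_subjects() -> list[Subject]:
    pairs = _case_pairs()
    # diagnostic subgroup layout: homozygotes 6 definite/probable + 4 possible,
    # heterozygotes 10 + 5, zero-copy 1 + 3 -> chromosome frequencies 64.7%
    # and 54.2%, homozygote frequencies 35.3% and 33.3% in the subgroups.
    dp_flags = [True] * 6 + [False] * 4 + [True] * 10 + [False] * 5 + [True] + [False] * 3
    dp_rank = 0
    subjects = []
    other_age = iter(_CASE_AGES_OTHER)
    hom_age = iter(_CASE_AGES_HOM)
    for i, (pair, dp) in enumerate(zip(pairs, dp_flags)):
        if dp:
            grade = DiagnosticGrade.DEFINITE if dp_rank < 13 else DiagnosticGrade.PROBABLE
            dp_rank += 1
        else:
            grade = DiagnosticGrade.POSSIBLE
        age = next(hom_age) if pair == (RISK, RISK) else next(other_age)
        subjects.append(Subject(
            id=f"CASE{i + 1:02d}", status=Status.CASE,
            sex=Sex.FEMALE if i < 12 else Sex.MALE,
            diagnostic_grade=grade, relatedness_grade=RelatednessGrade.CASE,
            age_years=age, genotype=genotype_of(pair), haplotypes=tuple(sorted(pair)),
        ))
    return subjects


def _control_subjects(prefix: str, pairs, grade: RelatednessGrade,
                      n_female: int, ages: list[float],
                      n_unknown_sex: int = 0) -> list[Subject]:
    subjects = []
    for i, pair in enumerate(pairs):
        if i < n_female:
            sex = Sex.FEMALE
        elif i >= len(pairs) - n_unknown_sex:
            sex = Sex.UNKNOWN
        else:
            sex = Sex.MALE
        subjects.append(Subject(
            id=f"{prefix}{i + 1:02d}", status=Status.CONTROL, sex=sex,
            relatedness_grade=grade, age_years=ages[i],
            genotype=genotype_of(pair), haplotypes=tuple(sorted(pair)),
        ))
    return subjects


def _unrelated_ages(pairs) -> list[float]:
    """Exactly 17 of the 46 unrelated controls are older than 8 years, carrying
    10 risk chromosomes among them (2 homozygotes, 6 heterozygotes)."""
    over8 = iter([9.5, 11.0] + [8.5, 9.0, 9.75, 10.5, 12.0, 13.83]
                 + [8.25, 8.75, 9.25, 10.0, 10.75, 11.5, 12.25, 12.75, 13.5])
    young = iter([0.58 + 0.3 * k for k in range(40)])
    quota = {2: 2, 1: 6, 0: 9}
    ages = []
    for pair in pairs:
        copies = sum(1 for h in pair if h == RISK)
        if quota[copies] > 0:
            quota[copies] -= 1
            ages.append(next(over8))
        else:
            ages.append(round(min(next(young), 7.9), 2))
    return ages


def reference_cohort(
    dose_variant: Literal["haplotype_counts", "dose_counts"] = "haplotype_counts",
) -> list[Subject]:
    """The 212-dog reference cohort with phased haplotypes attached.

    ``dose_variant='haplotype_counts'`` (default) matches the per-group haplotype
    chromosome counts exactly (risk-haplotype dose split 25/17/4 among
    unrelated controls: 25 risk chromosomes, 4 homozygous dogs);
    ``'dose_counts'`` matches the genotype-dose table exactly (24/18/4).
    The two differ by a single unrelated-control chromosome — the published
    tables cannot both be satisfied by one set of genotypes.
    """
    cases = _case_subjects()
    fd = _control_subjects(
        "FD", _first_degree_pairs(), RelatednessGrade.FIRST_DEGREE,
        n_female=56, ages=[round(1.0 + (0.123 * k) % 11.0, 2) for k in range(93)])
    sd = _control_subjects(
        "SD", _second_degree_pairs(), RelatednessGrade.SECOND_DEGREE,
        n_female=26, ages=[round(1.5 + (0.217 * k) % 10.5, 2) for k in range(44)])
    uc_pairs = _unrelated_pairs(dose_variant)
    uc = _control_subjects(
        "UC", uc_pairs, RelatednessGrade.UNRELATED,
        n_female=27, ages=_unrelated_ages(uc_pairs), n_unknown_sex=2)
    return cases + fd + sd + uc


def toy_library(filler_length: int = 16) -> AlleleLibrary:
    """Synthetic pre-aligned allele library covering all eleven haplotypes.

    Each locus's alleles share a constant filler and differ in a one-hot
    block: allele *i* carries G at block position *i* and A elsewhere, so the
    superposition of any unordered pair is unique (heterozygous pairs show R
    at exactly the two member positions). 8 DRB1, 7 DQA1 and 8 DQB1 alleles.
    """
    per_locus: dict[Locus, list[str]] = {loc: [] for loc in LOCI}
    for hap in ALL_HAPLOTYPES:
        for locus, name in zip(LOCI, hap):
            if name not in per_locus[locus]:
                per_locus[locus].append(name)
    alleles = []
    filler = ("ACGT" * ((filler_length // 4) + 1))[:filler_length]
    for locus in LOCI:
        names = sorted(per_locus[locus])
        k = len(names)
        for i, name in enumerate(names):
            block = "".join("G" if j == i else "A" for j in range(k))
            alleles.append(Allele(locus=locus, name=name, sequence=block + filler))
    return AlleleLibrary(alleles, provenance="synthetic one-hot toy library")
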