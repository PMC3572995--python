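"""Synthetic single-breed cohort generator with a dose-dependent disease model.

Emulates the statistical structure the pipeline assumes: a small pool of
three-locus DLA haplotypes segregating in one breed (founders drawn under
Hardy-Weinberg on haplotypes, no recombination within the tightly linked
block), nuclear families with Mendelian transmission, proband-based case
ascertainment, graded unaffected relatives (first-degree, second-degree) and
unrelated controls, and a logistic-odds disease model on risk-haplotype copy
number: odds(1 copy) = or_het * odds(0), odds(2 copies) = or_hom * odds(0).

Every stage of the pipeline (read emission -> typing -> phasing ->
association) can be exercised end-to-end against the generator's truth
records.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import yaml

from .phasing import Haplotype
from .reference import (
    DiagnosticGrade,
    Locus,
    RelatednessGrade,
    Sex,
    Status,
    Subject,
    ThreeLocusGenotype,
    AlleleLibrary,
)
from .sbt import NATIVE_ORIENTATION, AmbiguousRead, superpose
from Bio.Seq import Seq


class AscertainmentError(RuntimeError):
    """Could not accrue the requested number of cases; raise f0 or the ORs."""


#: Haplotype pool frequencies observed across all controls of the reference
#: breed cohort (counts per 366 chromosomes). The four rare haplotypes are
#: synthetic stand-ins for unnamed low-frequency haplotypes.
DEFAULT_POOL: dict[Haplotype, float] = {
    Haplotype("02001", "00401", "01303"): 162 / 366,
    Haplotype("00601", "005011", "00701"): 72 / 366,
    Haplotype("00801", "00301", "00401"): 44 / 366,
    Haplotype("00901", "00101", "008011"): 31 / 366,
    Haplotype("02301", "00301", "00501"): 25 / 366,
    Haplotype("01501", "00601", "02301"): 16 / 366,
    Haplotype("04801", "00101", "008011"): 9 / 366,
    Haplotype("01101", "00201", "01302"): 2 / 366,
    Haplotype("02001", "00901", "00101"): 2 / 366,
    Haplotype("00901", "00301", "00501"): 2 / 366,
    Haplotype("00801", "00401", "01303"): 1 / 366,
}

RISK_HAPLOTYPE = Haplotype("02001", "00401", "01303")


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic breed cohort.

    Defaults reproduce the reference study design: group sizes 29/93/44/46,
    diagnostic grades 13:4:12, dose odds ratios 5 (heterozygote) and 15
    (homozygote), and the control haplotype frequency spectrum. ``f0`` is the
    baseline penetrance of 0-copy dogs — a free parameter (true prevalence is
    not identifiable from a case-control design); 0.05 yields a few-percent
    population prevalence.
    """

    pool: dict[Haplotype, float] = field(default_factory=lambda: dict(DEFAULT_POOL))
    risk_haplotype: Haplotype = RISK_HAPLOTYPE
    f0: float = 0.05
    or_het: float = 5.0
    or_hom: float = 15.0
    n_cases: int = 29
    n_first: int = 93
    n_second: int = 44
    n_unrelated: int = 46
    grade_proportions: tuple[int, int, int] = (13, 4, 12)  # definite:probable:possible
    onset_log_median: float = 2.9   # years; log-normal, truncated to onset_range
    onset_log_sigma: float = 0.55
    onset_range: tuple[float, float] = (0.5, 8.0)
    control_age_range: tuple[float, float] = (0.58, 13.83)
    litter_mean: float = 4.0
    max_families: int = 20000
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.pool.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pool frequencies sum to {total}, not 1")
        if not 0.0 < self.f0 < 1.0:
            raise ValueError("f0 must be in (0,1)")
        if self.or_het < 1 or self.or_hom < 1:
            raise ValueError("dose odds ratios must be >= 1")
        if min(self.n_cases, self.n_first, self.n_second, self.n_unrelated) < 0:
            raise ValueError("group sizes must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "pool" in raw:
            raw["pool"] = {Haplotype.from_name(k): float(v) for k, v in raw["pool"].items()}
        if "risk_haplotype" in raw:
            raw["risk_haplotype"] = Haplotype.from_name(raw["risk_haplotype"])
        for key in ("grade_proportions", "onset_range", "control_age_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "pool": {h.name: float(f) for h, f in self.pool.items()},
            "risk_haplotype": self.risk_haplotype.name,
            "f0": self.f0, "or_het": self.or_het, "or_hom": self.or_hom,
            "n_cases": self.n_cases, "n_first": self.n_first,
            "n_second": self.n_second, "n_unrelated": self.n_unrelated,
            "grade_proportions": list(self.grade_proportions),
            "onset_log_median": self.onset_log_median,
            "onset_log_sigma": self.onset_log_sigma,
            "onset_range": list(self.onset_range),
            "control_age_range": list(self.control_age_range),
            "litter_mean": self.litter_mean,
            "max_families": self.max_families,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass
class TruthRecord:
    """Generating truth for one simulated dog."""

    id: str
    pair: tuple[Haplotype, Haplotype]
    copies: int
    affected: bool
    family: str = ""
    relation: str = "founder"  # founder|parent|offspring|grandparent|half_sib
    parents: tuple[str, str] = ("", "")


def affection_probability(copies: int, config: SimulationConfig) -> float:
    """Penetrance of a 0/1/2-copy genotype under the logistic-odds dose model."""
    if copies not in (0, 1, 2):
        raise ValueError("copies must be 0, 1 or 2")
    base_odds = config.f0 / (1.0 - config.f0)
    multiplier = {0: 1.0, 1: config.or_het, 2: config.or_hom}[copies]
    odds = base_odds * multiplier
    return odds / (1.0 + odds)


def _pool_arrays(config: SimulationConfig):
    haps = list(config.pool)
    freqs = np.array([config.pool[h] for h in haps], dtype=float)
    return haps, freqs / freqs.sum()


def draw_founder(config: SimulationConfig, rng: np.random.Generator) -> tuple[Haplotype, Haplotype]:
    """Two independent haplotype draws (random union of gametes within breed)."""
    haps, freqs = _pool_arrays(config)
    i, j = rng.choice(len(haps), size=2, p=freqs)
    return (haps[i], haps[j])


def _copies(pair: tuple[Haplotype, Haplotype], risk: Haplotype) -> int:
    return sum(1 for h in pair if h == risk)


def _is_affected(pair, config: SimulationConfig, rng: np.random.Generator) -> bool:
    return bool(rng.random() < affection_probability(_copies(pair, config.risk_haplotype), config))


def genotype_of(pair: tuple[Haplotype, Haplotype]) -> ThreeLocusGenotype:
    a, b = pair
    return ThreeLocusGenotype(
        drb1=(a.drb1, b.drb1), dqa1=(a.dqa1, b.dqa1), dqb1=(a.dqb1, b.dqb1)
    )


def _transmit(parent: tuple[Haplotype, Haplotype], rng) -> Haplotype:
    return parent[int(rng.integers(2))]


def build_families(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[list[Subject], dict[str, TruthRecord]]:
    """Simulate the full graded cohort by proband ascertainment.

    Three-generation nuclear families are generated (four grandparent
    founders, two parents, a litter of offspring, plus a paternal half-sib
    litter); affected offspring become cases until ``n_cases`` is reached.
    Unaffected parents and full siblings of a proband fill the first-degree
    group; unaffected grandparents and half-siblings the second-degree group;
    independent unaffected founders the unrelated controls. Relatives'
    affection status is drawn under the same dose model, so the unaffected
    groups are conditioned on being unaffected.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    truth: dict[str, TruthRecord] = {}
    cases: list[TruthRecord] = []
    first_pool: list[TruthRecord] = []
    second_pool: list[TruthRecord] = []
    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"D{counter[0]:05d}"

    n_families = 0
    while len(cases) < config.n_cases or len(first_pool) < config.n_first \
            or len(second_pool) < config.n_second:
        n_families += 1
        if n_families > config.max_families:
            raise AscertainmentError(
                f"{config.max_families} families without filling groups; "
                "increase f0 or the dose odds ratios"
            )
        fam = f"F{n_families:05d}"
        gps = [TruthRecord(new_id(), draw_founder(config, rng), 0, False, fam, "grandparent")
               for _ in range(4)]
        father_pair = (_transmit(gps[0].pair, rng), _transmit(gps[1].pair, rng))
        mother_pair = (_transmit(gps[2].pair, rng), _transmit(gps[3].pair, rng))
        father = TruthRecord(new_id(), father_pair, 0, False, fam, "parent",
                             (gps[0].id, gps[1].id))
        mother = TruthRecord(new_id(), mother_pair, 0, False, fam, "parent",
                             (gps[2].id, gps[3].id))
        n_kids = 1 + int(rng.poisson(config.litter_mean - 1))
        kids = [
            TruthRecord(new_id(), (_transmit(father_pair, rng), _transmit(mother_pair, rng)),
                        0, False, fam, "offspring", (father.id, mother.id))
            for _ in range(n_kids)
        ]
        # paternal half-sib litter (second-degree relatives of the proband)
        step = TruthRecord(new_id(), draw_founder(config, rng), 0, False, fam, "parent")
        n_half = 1 + int(rng.poisson(max(config.litter_mean - 2, 0.5)))
        half_sibs = [
            TruthRecord(new_id(), (_transmit(father_pair, rng), _transmit(step.pair, rng)),
                        0, False, fam, "half_sib", (father.id, step.id))
            for _ in range(n_half)
        ]
        members = gps + [father, mother, step] + kids + half_sibs
        for rec in members:
            rec.copies = _copies(rec.pair, config.risk_haplotype)
            rec.affected = _is_affected(rec.pair, config, rng)
            truth[rec.id] = rec
        affected_kids = [k for k in kids if k.affected]
        if not affected_kids:
            continue  # family not ascertained
        for k in affected_kids:
            if len(cases) < config.n_cases:
                cases.append(k)
        first_pool.extend(r for r in [father, mother] + kids
                          if not r.affected)
        second_pool.extend(r for r in gps + half_sibs if not r.affected)

    unrelated: list[TruthRecord] = []
    guard = 0
    while len(unrelated) < config.n_unrelated:
        guard += 1
        if guard > 100 * max(config.n_unrelated, 1) + 100:
            raise AscertainmentError("cannot accrue unaffected unrelated controls")
        rec = TruthRecord(new_id(), draw_founder(config, rng), 0, False, "", "founder")
        rec.copies = _copies(rec.pair, config.risk_haplotype)
        rec.affected = _is_affected(rec.pair, config, rng)
        if not rec.affected:
            truth[rec.id] = rec
            unrelated.append(rec)

    subjects = _assemble_subjects(
        cases, first_pool[: config.n_first], second_pool[: config.n_second],
        unrelated, config, rng,
    )
    kept = {s.id for s in subjects}
    truth = {sid: rec for sid, rec in truth.items() if sid in kept}
    return subjects, truth


def _assemble_subjects(cases, first, second, unrelated, config, rng) -> list[Subject]:
    subjects: list[Subject] = []
    lo, hi = config.onset_range
    mu = float(np.log(config.onset_log_median))
    n_def, n_prob, n_poss = config.grade_proportions
    grades = (
        [DiagnosticGrade.DEFINITE] * n_def
        + [DiagnosticGrade.PROBABLE] * n_prob
        + [DiagnosticGrade.POSSIBLE] * n_poss
    )
    for i, rec in enumerate(cases):
        onset = float(np.clip(rng.lognormal(mu, config.onset_log_sigma), lo, hi))
        grade = grades[i % len(grades)] if grades else DiagnosticGrade.POSSIBLE
        subjects.append(Subject(
            id=rec.id, status=Status.CASE, sex=_rand_sex(rng),
            diagnostic_grade=grade, relatedness_grade=RelatednessGrade.CASE,
            age_years=round(onset, 2), genotype=genotype_of(rec.pair),
        ))
    alo, ahi = config.control_age_range
    for pool, grade in ((first, RelatednessGrade.FIRST_DEGREE),
                        (second, RelatednessGrade.SECOND_DEGREE),
                        (unrelated, RelatednessGrade.UNRELATED)):
        for rec in pool:
            subjects.append(Subject(
                id=rec.id, status=Status.CONTROL, sex=_rand_sex(rng),
                relatedness_grade=grade,
                age_years=round(float(rng.uniform(alo, ahi)), 2),
                genotype=genotype_of(rec.pair),
            ))
    return subjects


def _rand_sex(rng) -> Sex:
    return Sex.FEMALE if rng.random() < 0.5 else Sex.MALE


def simulate_case_control(
    config: SimulationConfig,
    n_cases: int,
    n_controls: int,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[Subject], dict[str, TruthRecord]]:
    """Flat ascertained sampling: founders are drawn and kept as cases while
    affected (controls while unaffected) until both groups are filled. Used
    for parameter-recovery checks where family structure is not needed."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    haps, freqs = _pool_arrays(config)
    subjects: list[Subject] = []
    truth: dict[str, TruthRecord] = {}
    need_cases, need_controls = n_cases, n_controls
    penetrance = {k: affection_probability(k, config) for k in (0, 1, 2)}
    counter = 0
    guard = 0
    while need_cases > 0 or need_controls > 0:
        guard += 1
        if guard > 1000 * (n_cases + n_controls) + 1000:
            raise AscertainmentError("ascertained sampling did not terminate")
        batch = max(64, 2 * (need_cases + need_controls))
        idx = rng.choice(len(haps), size=(batch, 2), p=freqs)
        unif = rng.random(batch)
        for (i, j), u in zip(idx, unif):
            pair = (haps[i], haps[j])
            copies = _copies(pair, config.risk_haplotype)
            affected = bool(u < penetrance[copies])
            take_case = affected and need_cases > 0
            take_control = (not affected) and need_controls > 0
            if not (take_case or take_control):
                continue
            counter += 1
            sid = f"S{counter:05d}"
            truth[sid] = TruthRecord(sid, pair, copies, affected)
            if take_case:
                need_cases -= 1
                subjects.append(Subject(
                    id=sid, status=Status.CASE,
                    diagnostic_grade=DiagnosticGrade.DEFINITE,
                    relatedness_grade=RelatednessGrade.CASE,
                    genotype=genotype_of(pair)))
            else:
                need_controls -= 1
                subjects.append(Subject(
                    id=sid, status=Status.CONTROL,
                    relatedness_grade=RelatednessGrade.UNRELATED,
                    genotype=genotype_of(pair)))
            if need_cases == 0 and need_controls == 0:
                break
    return subjects, truth


def emit_reads(
    subjects: Iterable[Subject],
    library: AlleleLibrary,
    rng: Optional[np.random.Generator] = None,
) -> list[AmbiguousRead]:
    """Diploid consensus reads per dog per locus, in each locus's native
    Sanger orientation (antisense for DRB1/DQA1, sense for DQB1).

    Deterministic — there is no base-call error model; ``rng`` is accepted for
    interface symmetry and reserved for future error models.
    """
    reads: list[AmbiguousRead] = []
    for s in subjects:
        if s.genotype is None:
            continue
        for locus in Locus:
            pair = s.genotype.pair(locus)
            if pair is None:
                continue
            try:
                seq_a = library.get(locus, pair[0]).sequence
                seq_b = library.get(locus, pair[1]).sequence
            except KeyError as exc:
                raise ValueError(f"subject {s.id}: {exc}") from exc
            consensus = superpose(seq_a, seq_b)
            orientation = NATIVE_ORIENTATION[locus]
            if orientation == "antisense":
                consensus = str(Seq(consensus).reverse_complement())
            reads.append(AmbiguousRead(
                sample=s.id, locus=locus, sequence=consensus, orientation=orientation))
    return reads


def write_truth(truth: dict[str, TruthRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "hap1", "hap2", "copies", "affected",
                         "family", "relation", "parent1", "parent2"])
        for sid in sorted(truth):
            rec = truth[sid]
            writer.writerow([
                rec.id, rec.pair[0].name, rec.pair[1].name, rec.copies,
                int(rec.affected), rec.family, rec.relation,
                rec.parents[0], rec.parents[1],
            ])


def load_truth(path: str | Path) -> dict[str, TruthRecord]:
    out: dict[str, TruthRecord] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["id"]] = TruthRecord(
                id=row["id"],
                pair=(Haplotype.from_name(row["hap1"]), Haplotype.from_name(row["hap2"])),
                copies=int(row["copies"]), affected=bool(int(row["affected"])),
                family=row["family"], relation=row["relation"],
                parents=(row["parent1"], row["parent2"]),
            )
    return out
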