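"""Case-control contingency statistics for haplotype and allele associations.

Two counting units are kept explicit and never mixed:

* **chromosome** — each phased dog contributes two chromosomes; haplotype and
  allele frequencies and their odds ratios are per chromosome (the ``2n``
  convention of MHC association tables);
* **dog** — carrier/dose analyses classify dogs by copy number (0/1/2) of a
  target haplotype, with the 0-copy class as baseline.

Statistics follow the classical epidemiological toolkit: the cross-product
odds ratio, Yates-corrected chi-squared, its 1-df upper tail p-value, and the
Cornfield confidence interval obtained by inverting a continuity-corrected
chi statistic on the table refitted to its margins at each trial odds ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

from scipy.optimize import brentq
from scipy.stats import chi2 as _chi2_dist
from scipy.stats import norm as _norm

from .phasing import Haplotype
from .reference import (
    DiagnosticGrade,
    Locus,
    RelatednessGrade,
    Status,
    Subject,
)


class DegenerateTableError(ValueError):
    """A margin of the 2x2 table is zero; the statistic is undefined."""


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, bracket: tuple[float, float]):
        super().__init__(message)
        self.bracket = bracket


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure-by-status counts: a/b exposed/unexposed cases, c/d controls."""

    a: int
    b: int
    c: int
    d: int
    unit: str = "chromosome"  # chromosome | dog

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def require_margins(self) -> None:
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise DegenerateTableError(f"empty case or control group in {self}")
        if self.a + self.c == 0 or self.b + self.d == 0:
            raise DegenerateTableError(f"empty exposure margin in {self}")

    @property
    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)


def odds_ratio(t: TwoByTwo) -> float:
    """Cross-product odds ratio (a*d)/(b*c).

    Zero cells get the Haldane-Anscombe +0.5 adjustment to every cell; the raw
    table is unchanged and callers can see ``t.has_zero_cell``.
    """
    t.require_margins()
    if t.has_zero_cell:
        return ((t.a + 0.5) * (t.d + 0.5)) / ((t.b + 0.5) * (t.c + 0.5))
    return (t.a * t.d) / (t.b * t.c)


def yates_chi2(t: TwoByTwo) -> float:
    """Yates continuity-corrected chi-squared, floored at zero.

    n * (|ad - bc| - n/2)^2 / ((a+b)(c+d)(a+c)(b+d)); the correction is
    clamped so the statistic is 0 when |ad - bc| <= n/2.
    """
    t.require_margins()
    a, b, c, d, n = t.a, t.b, t.c, t.d, t.n
    dev = max(abs(a * d - b * c) - n / 2.0, 0.0)
    return n * dev * dev / ((a + b) * (c + d) * (a + c) * (b + d))


def chi2_p(chi2: float) -> float:
    """Upper-tail p-value of the 1-df chi-squared distribution."""
    if chi2 < 0:
        raise ValueError("chi2 must be nonnegative")
    return float(_chi2_dist.sf(chi2, df=1))


def _fitted_a(psi: float, t: TwoByTwo) -> float:
    """The exposed-case cell of the table refitted to the observed margins
    with odds ratio psi (root of the margin-preserving quadratic)."""
    m1 = t.a + t.b
    n1 = t.a + t.c
    n = t.n
    lo = max(0.0, m1 + n1 - n)
    hi = float(min(m1, n1))
    f = lambda x: x * (n - m1 - n1 + x) - psi * (m1 - x) * (n1 - x)
    eps = 1e-12 * max(1.0, hi)
    return brentq(f, lo + eps, hi - eps, xtol=1e-12)


def _cornfield_stat(psi: float, t: TwoByTwo, a_obs: float) -> float:
    fitted = _fitted_a(psi, t)
    b = (t.a + t.b) - fitted
    c = (t.a + t.c) - fitted
    d = t.n - (t.a + t.b) - (t.a + t.c) + fitted
    var_inv = 1.0 / fitted + 1.0 / b + 1.0 / c + 1.0 / d
    dev = max(abs(a_obs - fitted) - 0.5, 0.0)  # continuity correction
    return dev * dev * var_inv


def cornfield_ci(
    t: TwoByTwo,
    level: float = 0.95,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[float, float]:
    """Cornfield confidence interval for the odds ratio.

    Inverts the continuity-corrected chi statistic: each bound is the odds
    ratio at which the statistic on the margin-refitted table equals the
    normal critical value squared. Bisection/Brent root-finding between the
    point estimate and an expanding bracket. Always brackets the point OR.
    """
    t.require_margins()
    if t.has_zero_cell:
        t = TwoByTwo(t.a, t.b, t.c, t.d, unit=t.unit)  # raw retained by caller
        work = _HalfAdjusted(t)
        return cornfield_ci(work.table, level=level, tol=tol, max_iter=max_iter)
    z2 = float(_norm.ppf(1 - (1 - level) / 2) ** 2)
    point = odds_ratio(t)
    g = lambda psi: _cornfield_stat(psi, t, t.a) - z2

    # At psi -> inf the fitted cell approaches min(row, column margin); with the
    # continuity correction the statistic then tends to 0 when the observed cell
    # is within 0.5 of that margin, so the bound is genuinely unbounded
    # (likewise at psi -> 0 for the lower limit). This only arises on
    # Haldane-adjusted zero-cell tables.
    m1, n1, n = t.a + t.b, t.a + t.c, t.n
    upper_unbounded = t.a >= min(m1, n1) - 0.5
    lower_unbounded = t.a <= max(0, m1 + n1 - n) + 0.5

    def solve(direction: int) -> float:
        lo_factor, hi_factor = (1e-3, 1.0) if direction < 0 else (1.0, 1e3)
        left, right = point * lo_factor, point * hi_factor
        probe = left if direction < 0 else right
        for _ in range(max_iter):
            if g(probe) > 0:
                break
            probe = probe * (0.1 if direction < 0 else 10.0)
            if probe <= 0 or not math.isfinite(probe):
                raise ConvergenceError("cannot bracket Cornfield bound", (left, right))
        else:
            raise ConvergenceError("cannot bracket Cornfield bound", (left, right))
        lo, hi = (probe, point) if direction < 0 else (point, probe)
        try:
            return float(brentq(g, lo, hi, xtol=tol, maxiter=max_iter))
        except RuntimeError as exc:
            raise ConvergenceError(str(exc), (lo, hi)) from exc

    low = 0.0 if lower_unbounded else solve(-1)
    high = math.inf if upper_unbounded else solve(+1)
    return low, high


class _HalfAdjusted:
    """Haldane-Anscombe adjusted view used for zero-cell tables."""

    def __init__(self, t: TwoByTwo):
        # represented on a doubled scale to stay integral, then rescaled by
        # working directly with floats inside the Cornfield machinery
        self.table = _FloatTable(t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5, t.unit)


class _FloatTable(TwoByTwo):
    """Internal: TwoByTwo carrying non-integer (adjusted) cells."""

    def __init__(self, a, b, c, d, unit="chromosome"):
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "c", c)
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "unit", unit)


@dataclass
class AssociationResult:
    table: TwoByTwo
    odds_ratio: float
    ci_low: float
    ci_high: float
    chi2_yates: float
    p_value: float
    exposure: str = ""
    comparison: str = ""
    adjusted_for_zero_cell: bool = False

    @classmethod
    def from_table(cls, t: TwoByTwo, exposure: str = "", comparison: str = "") -> "AssociationResult":
        chi2 = yates_chi2(t)
        lo, hi = cornfield_ci(t)
        return cls(
            table=t, odds_ratio=odds_ratio(t), ci_low=lo, ci_high=hi,
            chi2_yates=chi2, p_value=chi2_p(chi2),
            exposure=exposure, comparison=comparison,
            adjusted_for_zero_cell=t.has_zero_cell,
        )


# --- cohort filters ---------------------------------------------------------

@dataclass(frozen=True)
class CohortFilter:
    """Declarative, composable subject filter.

    ``min_age_exclusive`` keeps subjects strictly older than the threshold
    (the "controls over 8 years" convention); subjects with missing age never
    pass an age filter.
    """

    status: Optional[Status] = None
    diagnostic_grades: Optional[frozenset[DiagnosticGrade]] = None
    relatedness_grades: Optional[frozenset[RelatednessGrade]] = None
    min_age_exclusive: Optional[float] = None

    def matches(self, s: Subject) -> bool:
        if self.status is not None and s.status is not self.status:
            return False
        if self.diagnostic_grades is not None and s.diagnostic_grade not in self.diagnostic_grades:
            return False
        if self.relatedness_grades is not None and s.relatedness_grade not in self.relatedness_grades:
            return False
        if self.min_age_exclusive is not None:
            if s.age_years is None or not s.age_years > self.min_age_exclusive:
                return False
        return True

    def apply(self, subjects: Iterable[Subject]) -> list[Subject]:
        return [s for s in subjects if self.matches(s)]


CASES = CohortFilter(status=Status.CASE)
ALL_CONTROLS = CohortFilter(status=Status.CONTROL)
UNRELATED_CONTROLS = CohortFilter(
    status=Status.CONTROL, relatedness_grades=frozenset({RelatednessGrade.UNRELATED})
)


def _phased(subjects: Iterable[Subject]) -> list[Subject]:
    return [s for s in subjects if s.haplotypes is not None]


def copies_of(s: Subject, target: Haplotype) -> int:
    assert s.haplotypes is not None
    return sum(1 for h in s.haplotypes if h == target)


# --- haplotype-level (chromosome) analyses ----------------------------------

def haplotype_table(
    subjects: Sequence[Subject],
    target: Haplotype,
    case_filter: CohortFilter = CASES,
    control_filter: CohortFilter = ALL_CONTROLS,
) -> TwoByTwo:
    """Chromosome-level 2x2 for one haplotype: each phased dog contributes two
    chromosomes, split into carrying/not carrying the target."""
    cases = _phased(case_filter.apply(subjects))
    controls = _phased(control_filter.apply(subjects))
    if not cases or not controls:
        raise DegenerateTableError("empty case or control group after filtering")
    a = sum(copies_of(s, target) for s in cases)
    c = sum(copies_of(s, target) for s in controls)
    return TwoByTwo(a=a, b=2 * len(cases) - a, c=c, d=2 * len(controls) - c,
                    unit="chromosome")


def haplotype_association(
    subjects: Sequence[Subject],
    target: Haplotype,
    case_filter: CohortFilter = CASES,
    control_filter: CohortFilter = ALL_CONTROLS,
    comparison: str = "",
) -> AssociationResult:
    t = haplotype_table(subjects, target, case_filter, control_filter)
    return AssociationResult.from_table(t, exposure=target.name, comparison=comparison)


# --- dog-level carrier / dose analyses --------------------------------------

@dataclass
class DoseClass:
    copies: int
    n_cases: int
    n_controls: int
    odds_ratio: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    degenerate: bool = False


@dataclass
class DoseResult:
    """Genotype-dose analysis: dogs classified by 0/1/2 copies of the target;
    odds ratios per class against the 0-copy baseline (baseline OR fixed at 1)."""

    target: Haplotype
    classes: dict[int, DoseClass] = field(default_factory=dict)

    @property
    def or_het(self) -> Optional[float]:
        return self.classes[1].odds_ratio

    @property
    def or_hom(self) -> Optional[float]:
        return self.classes[2].odds_ratio


def carrier_and_dose_tables(
    subjects: Sequence[Subject],
    target: Haplotype,
    case_filter: CohortFilter = CASES,
    control_filter: CohortFilter = UNRELATED_CONTROLS,
) -> DoseResult:
    cases = _phased(case_filter.apply(subjects))
    controls = _phased(control_filter.apply(subjects))
    if not cases or not controls:
        raise DegenerateTableError("empty case or control group after filtering")
    case_n = {k: sum(1 for s in cases if copies_of(s, target) == k) for k in (0, 1, 2)}
    ctl_n = {k: sum(1 for s in controls if copies_of(s, target) == k) for k in (0, 1, 2)}
    result = DoseResult(target=target)
    result.classes[0] = DoseClass(0, case_n[0], ctl_n[0], odds_ratio=1.0)
    if case_n[0] == 0 or ctl_n[0] == 0:
        for k in (1, 2):
            result.classes[k] = DoseClass(k, case_n[k], ctl_n[k], degenerate=True)
        result.classes[0].degenerate = True
        return result
    for k in (1, 2):
        cls = DoseClass(k, case_n[k], ctl_n[k])
        t = TwoByTwo(a=case_n[k], b=case_n[0], c=ctl_n[k], d=ctl_n[0], unit="dog")
        try:
            cls.odds_ratio = odds_ratio(t)
            cls.ci_low, cls.ci_high = cornfield_ci(t)
        except DegenerateTableError:
            cls.degenerate = True
        result.classes[k] = cls
    return result


# --- per-locus allelic association ------------------------------------------

def allelic_association(
    subjects: Sequence[Subject],
    locus: Locus,
    case_filter: CohortFilter = CASES,
    control_filter: CohortFilter = ALL_CONTROLS,
) -> dict[str, AssociationResult]:
    """Per-allele chromosome-level 2x2 tables at one locus, from genotypes
    alone (phasing not required). Degenerate alleles are skipped from the
    statistics but still counted."""
    def counts(group: list[Subject]) -> tuple[dict[str, int], int]:
        tally: dict[str, int] = {}
        chroms = 0
        for s in group:
            pair = s.genotype.pair(locus) if s.genotype else None
            if pair is None:
                continue
            chroms += 2
            for allele in pair:
                tally[allele] = tally.get(allele, 0) + 1
        return tally, chroms

    case_counts, case_2n = counts(case_filter.apply(subjects))
    ctl_counts, ctl_2n = counts(control_filter.apply(subjects))
    if case_2n == 0 or ctl_2n == 0:
        raise DegenerateTableError("no typed chromosomes in one group")
    out: dict[str, AssociationResult] = {}
    for allele in sorted(set(case_counts) | set(ctl_counts)):
        a = case_counts.get(allele, 0)
        c = ctl_counts.get(allele, 0)
        t = TwoByTwo(a=a, b=case_2n - a, c=c, d=ctl_2n - c, unit="chromosome")
        try:
            out[allele] = AssociationResult.from_table(
                t, exposure=f"{locus.value}*{allele}")
        except DegenerateTableError:
            out[allele] = AssociationResult(
                table=t, odds_ratio=float("nan"), ci_low=float("nan"),
                ci_high=float("nan"), chi2_yates=float("nan"), p_value=float("nan"),
                exposure=f"{locus.value}*{allele}", comparison="degenerate",
            )
    return out


# --- graded-control frequency gradient --------------------------------------

STRATUM_ORDER = ("cases", "first_degree", "second_degree", "unrelated")

_STRATUM_FILTERS: dict[str, CohortFilter] = {
    "cases": CASES,
    "first_degree": CohortFilter(
        status=Status.CONTROL, relatedness_grades=frozenset({RelatednessGrade.FIRST_DEGREE})),
    "second_degree": CohortFilter(
        status=Status.CONTROL, relatedness_grades=frozenset({RelatednessGrade.SECOND_DEGREE})),
    "unrelated": UNRELATED_CONTROLS,
}


@dataclass
class StratumFrequency:
    stratum: str
    two_n: int
    carrier_chromosomes: int
    haplotype_freq_pct: float
    homozygote_dogs: int
    homozygote_freq_pct: float


@dataclass
class GroupFrequencyProfile:
    """Risk-haplotype frequency by graded stratum, cases -> unrelated.

    ``monotone_decreasing`` flags whether the chromosome frequency is
    non-increasing along the relatedness gradient — the pattern expected of a
    low-penetrance risk haplotype enriched in case pedigrees."""

    target: Haplotype
    strata: list[StratumFrequency]
    monotone_decreasing: bool
    warnings: list[str] = field(default_factory=list)


def gradient_profile(subjects: Sequence[Subject], target: Haplotype) -> GroupFrequencyProfile:
    strata: list[StratumFrequency] = []
    warnings: list[str] = []
    for name in STRATUM_ORDER:
        group = _phased(_STRATUM_FILTERS[name].apply(subjects))
        if not group:
            warnings.append(f"stratum {name} empty; omitted")
            continue
        two_n = 2 * len(group)
        carriers = sum(copies_of(s, target) for s in group)
        homs = sum(1 for s in group if copies_of(s, target) == 2)
        strata.append(StratumFrequency(
            stratum=name, two_n=two_n, carrier_chromosomes=carriers,
            haplotype_freq_pct=100.0 * carriers / two_n,
            homozygote_dogs=homs,
            homozygote_freq_pct=100.0 * homs / len(group),
        ))
    freqs = [s.haplotype_freq_pct for s in strata]
    monotone = all(x >= y for x, y in zip(freqs, freqs[1:]))
    return GroupFrequencyProfile(target=target, strata=strata,
                                 monotone_decreasing=monotone, warnings=warnings)
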