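"""Contingency statistics: OR, Yates chi2, p, Cornfield CI, cohort analyses."""

import math

import numpy as np
import pytest

from dlahap.association import (
    ALL_CONTROLS,
    CASES,
    UNRELATED_CONTROLS,
    CohortFilter,
    DegenerateTableError,
    TwoByTwo,
    allelic_association,
    carrier_and_dose_tables,
    chi2_p,
    cornfield_ci,
    gradient_profile,
    haplotype_table,
    odds_ratio,
    yates_chi2,
)
from dlahap.datasets import H3, H7, RISK
from dlahap.reference import DiagnosticGrade, Locus, RelatednessGrade, Status

ALL_TABLE = TwoByTwo(35, 23, 162, 204)
UNREL_TABLE = TwoByTwo(35, 23, 25, 67)


class TestOddsRatio:
    def test_headline_tables(self):
        assert odds_ratio(ALL_TABLE) == pytest.approx(1.92, abs=0.005)
        assert odds_ratio(UNREL_TABLE) == pytest.approx(4.08, abs=0.005)

    def test_null_table_gives_one(self):
        assert odds_ratio(TwoByTwo(10, 20, 5, 10)) == 1.0

    def test_symmetry_inverse(self):
        t = TwoByTwo(7, 13, 29, 31)
        assert odds_ratio(t) * odds_ratio(TwoByTwo(13, 7, 31, 29)) == pytest.approx(1.0)

    def test_zero_cell_gets_haldane_adjustment(self):
        t = TwoByTwo(5, 5, 0, 10)
        assert odds_ratio(t) == pytest.approx((5.5 * 10.5) / (5.5 * 0.5))

    def test_empty_margin_degenerate(self):
        with pytest.raises(DegenerateTableError):
            odds_ratio(TwoByTwo(0, 0, 5, 5))


class TestYatesChi2:
    def test_headline_tables(self):
        assert yates_chi2(ALL_TABLE) == pytest.approx(4.58, abs=0.005)
        assert yates_chi2(UNREL_TABLE) == pytest.approx(15.0, abs=0.5)

    def test_equal_proportions_zero(self):
        assert yates_chi2(TwoByTwo(10, 10, 10, 10)) == 0.0

    def test_correction_floored_at_zero(self):
        # |ad - bc| = 10 < n/2 = 20: statistic clamps to 0 instead of going negative
        assert yates_chi2(TwoByTwo(11, 10, 10, 9)) == 0.0

    def test_invariant_under_transpose(self):
        t = TwoByTwo(12, 5, 9, 22)
        transposed = TwoByTwo(12, 9, 5, 22)
        assert yates_chi2(t) == pytest.approx(yates_chi2(transposed))


class TestChi2P:
    def test_published_rounding(self):
        assert round(chi2_p(yates_chi2(ALL_TABLE)), 3) == 0.032
        assert chi2_p(yates_chi2(UNREL_TABLE)) == pytest.approx(0.00011, abs=0.00002)

    def test_zero_statistic_gives_one(self):
        assert chi2_p(0.0) == 1.0

    def test_critical_value(self):
        assert chi2_p(3.841) == pytest.approx(0.050, abs=0.0005)

    def test_strictly_decreasing(self):
        xs = np.linspace(0, 30, 50)
        ps = [chi2_p(x) for x in xs]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestCornfieldCI:
    @pytest.mark.parametrize("table,printed", [
        (ALL_TABLE, (1.05, 3.5)),
        (UNREL_TABLE, (1.92, 8.74)),
        (TwoByTwo(35, 23, 10, 24), (1.35, 10.04)),
        (TwoByTwo(15, 4, 18, 24, unit="dog"), (1.25, 21.67)),
        (TwoByTwo(10, 4, 4, 24, unit="dog"), (2.54, 104.45)),
    ])
    def test_reproduces_published_intervals_within_ten_percent(self, table, printed):
        lo, hi = cornfield_ci(table)
        assert lo == pytest.approx(printed[0], rel=0.10)
        assert hi == pytest.approx(printed[1], rel=0.10)

    def test_interval_brackets_point_estimate(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            t = TwoByTwo(*(int(x) for x in rng.integers(1, 60, size=4)))
            lo, hi = cornfield_ci(t)
            assert lo < odds_ratio(t) < hi

    def test_interval_narrows_with_scaled_counts(self):
        t = TwoByTwo(12, 8, 9, 21)
        lo1, hi1 = cornfield_ci(t)
        for k in (2, 4):
            lok, hik = cornfield_ci(TwoByTwo(12 * k, 8 * k, 9 * k, 21 * k))
            assert hik / lok < hi1 / lo1
            lo1, hi1 = lok, hik

    def test_zero_cell_handled_via_adjustment(self):
        # adjusted observed cell touches its margin: upper limit is unbounded
        lo, hi = cornfield_ci(TwoByTwo(8, 4, 0, 12))
        assert 0 < lo < odds_ratio(TwoByTwo(8, 4, 0, 12))
        assert hi == math.inf


DP = CohortFilter(status=Status.CASE,
                  diagnostic_grades=frozenset({DiagnosticGrade.DEFINITE,
                                               DiagnosticGrade.PROBABLE}))
POSS = CohortFilter(status=Status.CASE,
                    diagnostic_grades=frozenset({DiagnosticGrade.POSSIBLE}))
OVER8 = CohortFilter(status=Status.CONTROL,
                     relatedness_grades=frozenset({RelatednessGrade.UNRELATED}),
                     min_age_exclusive=8.0)


class TestHaplotypeTable:
    def test_cases_vs_all_controls_counts(self, cohort_haplotype_counts):
        t = haplotype_table(cohort_haplotype_counts, RISK)
        assert (t.a, t.b, t.c, t.d) == (35, 23, 162, 204)

    def test_cases_vs_unrelated_counts(self, cohort_haplotype_counts):
        t = haplotype_table(cohort_haplotype_counts, RISK, control_filter=UNRELATED_CONTROLS)
        assert (t.a, t.b, t.c, t.d) == (35, 23, 25, 67)

    def test_chromosome_bookkeeping(self, cohort_haplotype_counts):
        for target in (RISK, H3, H7):
            t = haplotype_table(cohort_haplotype_counts, target)
            assert t.a + t.b == 2 * 29
            assert t.c + t.d == 2 * 183

    def test_absent_target_zero_exposed(self, cohort_haplotype_counts):
        from dlahap.phasing import Haplotype

        t = haplotype_table(cohort_haplotype_counts, Haplotype("zzz", "zzz", "zzz"))
        assert t.a == 0 and t.c == 0

    def test_empty_group_degenerate(self, cohort_haplotype_counts):
        nothing = CohortFilter(status=Status.CONTROL, min_age_exclusive=99.0)
        with pytest.raises(DegenerateTableError):
            haplotype_table(cohort_haplotype_counts, RISK, control_filter=nothing)


class TestDose:
    def test_dose_counts_and_odds_ratios(self, cohort_dose_counts):
        dose = carrier_and_dose_tables(cohort_dose_counts, RISK)
        assert (dose.classes[0].n_cases, dose.classes[1].n_cases,
                dose.classes[2].n_cases) == (4, 15, 10)
        assert (dose.classes[0].n_controls, dose.classes[1].n_controls,
                dose.classes[2].n_controls) == (24, 18, 4)
        assert dose.or_het == pytest.approx(5.0)
        assert dose.or_hom == pytest.approx(15.0)
        assert dose.classes[0].odds_ratio == 1.0

    def test_het_or_is_cross_product(self):
        assert (15 * 24) / (4 * 18) == 5.0  # identity behind the reported value

    def test_all_zero_copy_degenerate(self, cohort_dose_counts):
        from dlahap.phasing import Haplotype

        dose = carrier_and_dose_tables(cohort_dose_counts, Haplotype("z", "z", "z"))
        assert dose.classes[1].degenerate and dose.classes[2].degenerate


class TestSubgroups:
    def test_diagnostic_grade_filters_select_17_and_12(self, cohort_haplotype_counts):
        assert len(DP.apply(cohort_haplotype_counts)) == 17
        assert len(POSS.apply(cohort_haplotype_counts)) == 12

    def test_subgroup_odds_ratios(self, cohort_haplotype_counts):
        t_dp = haplotype_table(cohort_haplotype_counts, RISK, DP, UNRELATED_CONTROLS)
        t_poss = haplotype_table(cohort_haplotype_counts, RISK, POSS, UNRELATED_CONTROLS)
        assert odds_ratio(t_dp) == pytest.approx(4.91, abs=0.005)
        assert odds_ratio(t_poss) == pytest.approx(3.17, abs=0.005)
        # subgroup chromosome frequencies
        assert 100 * t_dp.a / (t_dp.a + t_dp.b) == pytest.approx(64.7, abs=0.05)
        assert 100 * t_poss.a / (t_poss.a + t_poss.b) == pytest.approx(54.2, abs=0.05)

    def test_controls_over_eight_years(self, cohort_haplotype_counts):
        assert len(OVER8.apply(cohort_haplotype_counts)) == 17
        t = haplotype_table(cohort_haplotype_counts, RISK, control_filter=OVER8)
        assert odds_ratio(t) == pytest.approx(3.65, abs=0.005)
        assert 100 * t.c / (t.c + t.d) == pytest.approx(29.4, abs=0.05)

    def test_age_filter_strict_and_missing_age_never_passes(self, cohort_haplotype_counts):
        import dataclasses

        age_filter = CohortFilter(min_age_exclusive=1.0)
        old = next(s for s in cohort_haplotype_counts if s.age_years and s.age_years > 1.0)
        assert age_filter.matches(old)
        boundary = dataclasses.replace(old, age_years=1.0)
        assert not age_filter.matches(boundary)  # strictly greater than
        assert not age_filter.matches(dataclasses.replace(old, age_years=None))


class TestAllelic:
    def test_dqa1_00101_pools_across_carrying_haplotypes(self, cohort_haplotype_counts):
        # DQA1*00101 rides on two haplotypes; chromosome counts add across them
        results = allelic_association(cohort_haplotype_counts, Locus.DQA1,
                                      control_filter=UNRELATED_CONTROLS)
        t = results["00101"].table
        assert t.a == 5        # case chromosomes
        assert t.c == 11       # unrelated-control chromosomes
        assert t.a + t.b == 58 and t.c + t.d == 92

    def test_allele_frequencies_partition_each_group(self, cohort_haplotype_counts):
        for locus in Locus:
            results = allelic_association(cohort_haplotype_counts, locus)
            assert sum(r.table.a for r in results.values()) == 58
            assert sum(r.table.c for r in results.values()) == 366

    def test_protective_haplotype_carriers_match_reported_counts(self, cohort_haplotype_counts):
        from dlahap.datasets import PROTECTIVE
        from dlahap.association import copies_of

        unrel = UNRELATED_CONTROLS.apply(cohort_haplotype_counts)
        cases = CASES.apply(cohort_haplotype_counts)
        assert sum(1 for s in unrel if copies_of(s, PROTECTIVE) >= 1) == 9
        assert sum(1 for s in cases if copies_of(s, PROTECTIVE) >= 1) == 1


class TestGradient:
    def test_reference_gradient_values_and_monotonicity(self, cohort_haplotype_counts):
        profile = gradient_profile(cohort_haplotype_counts, RISK)
        freqs = {s.stratum: s.haplotype_freq_pct for s in profile.strata}
        assert freqs["cases"] == pytest.approx(60.3, abs=0.05)
        assert freqs["first_degree"] == pytest.approx(51.6, abs=0.05)
        assert freqs["second_degree"] == pytest.approx(46.6, abs=0.05)
        assert freqs["unrelated"] == pytest.approx(27.2, abs=0.05)
        assert profile.monotone_decreasing
        homs = {s.stratum: s.homozygote_freq_pct for s in profile.strata}
        assert homs["cases"] == pytest.approx(34.5, abs=0.05)
        assert homs["unrelated"] == pytest.approx(8.7, abs=0.05)

    def test_single_stratum_trivially_monotone(self, cohort_haplotype_counts):
        only_cases = [s for s in cohort_haplotype_counts if s.status is Status.CASE]
        profile = gradient_profile(only_cases, RISK)
        assert len(profile.strata) == 1
        assert profile.monotone_decreasing
        assert profile.warnings

    def test_null_simulation_monotone_near_chance_rate(self):
        # with no disease effect the four strata are exchangeable, so a strictly
        # decreasing ordering occurs at ~1/4! = 4.2% of runs
        from dlahap.reference import (RelatednessGrade, Status as St, Subject)
        from dlahap.simulate import SimulationConfig, draw_founder, genotype_of

        cfg = SimulationConfig(or_het=1.0, or_hom=1.0)
        rng = np.random.default_rng(314)
        hits = 0
        reps = 200
        for _ in range(reps):
            subjects = []
            for stratum, (status, rel) in enumerate([
                (St.CASE, RelatednessGrade.CASE),
                (St.CONTROL, RelatednessGrade.FIRST_DEGREE),
                (St.CONTROL, RelatednessGrade.SECOND_DEGREE),
                (St.CONTROL, RelatednessGrade.UNRELATED),
            ]):
                for i in range(25):
                    pair = draw_founder(cfg, rng)
                    kw = {}
                    if status is St.CASE:
                        kw["diagnostic_grade"] = DiagnosticGrade.POSSIBLE
                    subjects.append(Subject(
                        id=f"s{stratum}_{i}", status=status, relatedness_grade=rel,
                        genotype=genotype_of(pair), haplotypes=tuple(sorted(pair)),
                        **kw))
            if gradient_profile(subjects, RISK).monotone_decreasing:
                hits += 1
        # binomial(200, ~0.042 plus ties): allow a generous 3-SE style band
        assert hits / reps < 0.15
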