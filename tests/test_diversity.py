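"""Frequency spectra and the forensic diversity statistics (GD/HD/HMP/DC)."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ystrpop import (
    FrequencySpectrum,
    allele_spectrum,
    diversity_stats,
    discrimination_capacity,
    gene_diversity,
    haplotype_spectrum,
    match_probability,
    panel_report,
    subset_panel,
)
from ystrpop.model import (
    Haplotype,
    PanelDefinition,
    PopulationSample,
    parse_allele,
)
from ystrpop.panels import MINIMAL, POWERPLEX_Y, YFILER
from ystrpop.simulate import SimulationConfig, sample_from_spectrum, simulate_population

from oracles import brute_group_counts, brute_match_probability


def _one_locus_sample(alleles, locus="DYS19"):
    haps = tuple(
        Haplotype(sample_id=f"S{i}", calls={locus: parse_allele(str(a), locus)})
        for i, a in enumerate(alleles)
    )
    return PopulationSample(name="toy", haplotypes=haps)


class TestAlleleSpectrum:
    def test_hand_counted_spectrum(self):
        spec = allele_spectrum(_one_locus_sample([10, 10, 12]), "DYS19")
        assert sorted(c for _, c in spec.states) == [1, 2]
        assert sorted(spec.frequencies) == pytest.approx([1 / 3, 2 / 3])

    def test_monomorphic_locus(self):
        spec = allele_spectrum(_one_locus_sample([14] * 5), "DYS19")
        assert spec.n_distinct == 1
        assert spec.frequencies == (1.0,)

    def test_singleton_among_312_gives_printed_lower_bound(self):
        spec = allele_spectrum(_one_locus_sample([15] * 311 + [16]), "DYS19")
        assert round(min(spec.frequencies), 4) == 0.0032

    def test_multicopy_state_is_the_whole_call(self):
        sample = _one_locus_sample(["13,17", "13,17", "13,18"], locus="DYS385")
        spec = allele_spectrum(sample, "DYS385")
        assert spec.n_distinct == 2  # unordered pairs count as single states

    def test_untyped_locus_raises(self):
        with pytest.raises(ValueError, match="DYS390"):
            allele_spectrum(_one_locus_sample([10]), "DYS390")


class TestSpectrumInvariants:
    def test_frequencies_sum_to_one(self):
        spec = FrequencySpectrum.from_counts([5, 3, 2, 1, 1])
        assert sum(spec.frequencies) == pytest.approx(1.0, abs=1e-12)

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            FrequencySpectrum(states=(("a", 2),), n=3)

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            FrequencySpectrum(states=(("a", 0), ("b", 3)), n=3)


class TestDiversityFormulas:
    def test_single_state_has_zero_diversity(self):
        spec = FrequencySpectrum.from_counts([7])
        assert gene_diversity(spec) == 0.0
        assert match_probability(spec) == 1.0
        assert discrimination_capacity(spec) == pytest.approx(1 / 7)

    def test_two_distinct_of_two_is_maximal(self):
        spec = FrequencySpectrum.from_counts([1, 1])
        assert gene_diversity(spec) == pytest.approx(1.0)

    def test_diversity_undefined_below_two(self):
        with pytest.raises(ValueError):
            gene_diversity(FrequencySpectrum.from_counts([1]))

    @pytest.mark.parametrize("k", [2, 5, 10])
    def test_uniform_spectrum_match_probability_is_reciprocal(self, k):
        spec = FrequencySpectrum.from_counts([3] * k)
        assert match_probability(spec) == pytest.approx(1 / k)

    @given(st.lists(st.integers(1, 6), min_size=2, max_size=20))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bounds_and_identities(self, counts):
        spec = FrequencySpectrum.from_counts(counts)
        gd = gene_diversity(spec)
        hmp = match_probability(spec)
        dc = discrimination_capacity(spec)
        assert 0.0 <= gd <= 1.0
        assert hmp >= 1 / spec.n - 1e-12
        assert 0 < dc <= 1.0
        assert round(dc * spec.n) == spec.n_distinct  # DC*n is an integer
        # equality HMP == 1/n iff all states unique
        if all(c == 1 for c in counts):
            assert hmp == pytest.approx(1 / spec.n)

    def test_large_n_limit_approaches_expected_heterozygosity(self):
        # fixed Pi = (0.5, 0.5): GD -> 1 - sum Pi^2 = 0.5 as n grows
        small = gene_diversity(FrequencySpectrum.from_counts([5, 5]))
        large = gene_diversity(FrequencySpectrum.from_counts([5000, 5000]))
        assert abs(large - 0.5) < abs(small - 0.5)
        assert large == pytest.approx(0.5, abs=1e-4)


class TestHaplotypeSpectrum:
    def test_single_individual(self, yfiler_panel):
        cfg = SimulationConfig(n_individuals=1, panel=yfiler_panel, seed=0)
        spec = haplotype_spectrum(simulate_population(cfg), yfiler_panel)
        assert spec.n == 1 and spec.n_distinct == 1

    def test_counts_match_brute_force_grouping(self, small_cohort, yfiler_panel):
        spec = haplotype_spectrum(small_cohort, yfiler_panel)
        expected = brute_group_counts(small_cohort.haplotypes, yfiler_panel.loci)
        assert sorted((c for _, c in spec.states), reverse=True) == expected

    def test_match_probability_equals_ordered_pair_fraction(self, yfiler_panel):
        cfg = SimulationConfig(n_individuals=20, panel=yfiler_panel,
                               generations=500, seed=9)
        sample = simulate_population(cfg)
        spec = haplotype_spectrum(sample, yfiler_panel)
        assert match_probability(spec) == pytest.approx(
            brute_match_probability(sample.haplotypes, yfiler_panel.loci)
        )

    def test_individuals_missing_a_panel_locus_are_excluded(self):
        panel = PanelDefinition(name="p2", loci=("DYS19", "DYS390"))
        haps = (
            Haplotype("A", {"DYS19": parse_allele("14", "DYS19"),
                            "DYS390": parse_allele("22", "DYS390")}),
            Haplotype("B", {"DYS19": parse_allele("15", "DYS19")}),  # incomplete
        )
        spec = haplotype_spectrum(PopulationSample("p", haps), panel)
        assert spec.n == 1
        # ...but B still contributes to the per-locus spectrum at DYS19
        assert allele_spectrum(PopulationSample("p", haps), "DYS19").n == 2


class TestPanelMonotonicity:
    @pytest.mark.parametrize("seed", [1, 2, 3, 4])
    def test_nested_panels_dc_hd_hmp(self, seed):
        cfg = SimulationConfig(n_individuals=50, panel=YFILER, seed=seed,
                               generations=400)
        sample = simulate_population(cfg)
        stats = [
            diversity_stats(haplotype_spectrum(subset_panel(sample, p), p))
            for p in (MINIMAL, POWERPLEX_Y, YFILER)
        ]
        for prev, cur in zip(stats, stats[1:]):
            assert cur.dc >= prev.dc
            assert cur.gd_or_hd >= prev.gd_or_hd - 1e-12
            assert cur.hmp <= prev.hmp + 1e-12


class TestPanelReport:
    def test_full_panel_row_equals_whole_sample_stats(self, small_cohort, yfiler_panel):
        report = panel_report(small_cohort, [yfiler_panel])
        stats = diversity_stats(haplotype_spectrum(small_cohort, yfiler_panel))
        row = report.iloc[0]
        assert row["DC"] == pytest.approx(stats.dc)
        assert row["HD"] == pytest.approx(stats.gd_or_hd)
        assert row["HMP"] == pytest.approx(stats.hmp)
        assert row["n_markers"] == yfiler_panel.marker_count

    def test_single_locus_panels_equal_per_locus_spectra(self, small_cohort):
        p1 = PanelDefinition(name="only_DYS19", loci=("DYS19",))
        p2 = PanelDefinition(name="only_DYS390", loci=("DYS390",))
        report = panel_report(small_cohort, [p1, p2])
        for row, locus in zip(report.itertuples(), ("DYS19", "DYS390")):
            spec = allele_spectrum(small_cohort, locus)
            assert row.HD == pytest.approx(gene_diversity(spec))
            assert row.HMP == pytest.approx(match_probability(spec))

    def test_report_order_follows_input(self, small_cohort):
        report = panel_report(small_cohort, [POWERPLEX_Y, MINIMAL])
        assert list(report["panel"]) == ["powerplex_y", "minimal"]


class TestSpectrumConstrainedSample:
    def test_printed_study_spectrum(self, full_panel):
        sample = sample_from_spectrum([(1, 296), (2, 8)], full_panel, seed=5)
        stats = diversity_stats(haplotype_spectrum(sample, full_panel))
        assert (stats.n, stats.n_distinct, stats.n_unique) == (312, 304, 296)
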