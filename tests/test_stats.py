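import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import build_catalog
from radscape.errors import ConfigurationError, DegenerateInputError
from radscape.io import HaplotypeAlignment, HaplotypeTable, PopulationMap, seq_to_codes
from radscape.stats import (
    haplotype_diversity,
    hudson_fst,
    individual_heterozygosity,
    k2p_distance,
    nucleotide_diversity,
    p_distance,
    pairwise_difference_matrix,
    region_heterozygosity,
    strict_clock_time,
    summary_stats,
    tajimas_d,
    wc_fst,
)


class TestPDistance:
    @pytest.mark.parametrize(
        "subs,expected_pct",
        [(3, 0.46), (8, 1.22), (11, 1.67)],  # barcoding-fragment separations
    )
    def test_658bp_substitution_counts(self, subs, expected_pct):
        a = "A" * 658
        b = "G" * subs + "A" * (658 - subs)
        n, prop = p_distance(a, b)
        assert n == subs
        assert round(100 * prop, 2) == expected_pct

    def test_identical_sequences(self):
        assert p_distance("ACGT", "ACGT") == (0, 0.0)

    def test_pairwise_deletion(self):
        n, prop = p_distance("ACGN", "ACTT")
        assert (n, prop) == (1, 1 / 3)

    def test_no_comparable_sites_raises(self):
        with pytest.raises(DegenerateInputError):
            p_distance("NNN", "ACG")


class TestK2P:
    def test_identical(self):
        assert k2p_distance("ACGT", "ACGT") == 0.0

    def test_pure_transitions(self):
        # P=0.1, Q=0 -> -0.5*ln((1-0.2)*sqrt(1)) = -0.5*ln(0.8)
        a, b = "A" * 100, "G" * 10 + "A" * 90
        assert k2p_distance(a, b) == pytest.approx(-0.5 * math.log(0.8), rel=1e-12)

    def test_pure_transversions(self):
        # P=0, Q=0.1 -> -0.5*ln(0.9) - 0.25*ln(0.8)  (ape::dist.dna K80 agrees)
        a, b = "A" * 100, "C" * 10 + "A" * 90
        expected = -0.5 * math.log(0.9) - 0.25 * math.log(0.8)
        assert k2p_distance(a, b) == pytest.approx(expected, rel=1e-12)

    def test_saturation_flags_infinite(self):
        assert math.isinf(k2p_distance("ACAC", "GTGT"))


class TestHeterozygosity:
    def make(self):
        inds = ["lowA", "lowB", "high"]
        pm = PopulationMap(inds, {i: "s" for i in inds},
                           {"lowA": "L", "lowB": "L", "high": "H"})
        block = np.zeros((4, 3, 2), np.int8)
        block[0, 2] = (0, 1)
        block[1, 2] = (0, 1)
        block[2, 2] = (0, 1)
        block[0, 0] = (0, 1)  # lowA: 1 het of 4
        return build_catalog([block], inds, pm), pm

    def test_all_homozygous_individual(self):
        cat, _ = self.make()
        assert individual_heterozygosity(cat, "lowB") == 0.0

    def test_one_het_of_four(self):
        cat, _ = self.make()
        assert individual_heterozygosity(cat, "lowA") == 0.25

    def test_region_mean_and_sd(self):
        cat, pm = self.make()
        res = region_heterozygosity(cat, pm)
        assert res["H"][0] == 0.75
        assert res["L"][0] == pytest.approx(0.125)
        assert res["L"][1] == pytest.approx(np.std([0.25, 0.0], ddof=1))


class TestDiversity:
    def test_haplotype_diversity_examples(self):
        t = HaplotypeTable(np.zeros((1, 4), np.int8), {"all": np.array([4])}, {})
        assert haplotype_diversity(t) == 0.0
        t2 = HaplotypeTable(np.zeros((2, 4), np.int8), {"all": np.array([1, 1])}, {})
        assert haplotype_diversity(t2) == 1.0
        t3 = HaplotypeTable(np.zeros((2, 4), np.int8), {"all": np.array([3, 1])}, {})
        assert haplotype_diversity(t3) == pytest.approx(0.5)

    def test_pi_simple(self):
        codes = np.vstack([seq_to_codes("AAAAAAAAAA"), seq_to_codes("AAAAAAAAAT")])
        assert nucleotide_diversity(codes) == pytest.approx(0.1)

    @given(st.integers(min_value=0, max_value=10_000))
    def test_pi_equals_bruteforce_mean_pairwise(self, seed):
        rng = np.random.default_rng(seed)
        n, L = rng.integers(2, 7), rng.integers(4, 30)
        codes = rng.integers(0, 4, size=(n, L)).astype(np.int8)
        codes[rng.random(size=(n, L)) < 0.1] = -1
        pairs = []
        for i, j in itertools.combinations(range(n), 2):
            both = (codes[i] >= 0) & (codes[j] >= 0)
            if both.sum():
                pairs.append(np.sum(codes[i][both] != codes[j][both]) / both.sum())
        if not pairs:
            return
        assert nucleotide_diversity(codes) == pytest.approx(float(np.mean(pairs)))


class TestTajimasD:
    def test_hand_built_alignment_matches_direct_formula(self):
        # n=4, S=3: evaluate Tajima's definition step by step, independently
        codes = np.vstack([
            seq_to_codes("AAAAAAAAAA"),
            seq_to_codes("TAAAAAAAAA"),
            seq_to_codes("TCAAAAAAAA"),
            seq_to_codes("TCGAAAAAAA"),
        ])
        n, S = 4, 3
        diffs = [1, 2, 3, 1, 2, 1]  # all 6 pairs, counted by hand
        k_hat = sum(diffs) / 6
        a1 = 1 + 1 / 2 + 1 / 3
        a2 = 1 + 1 / 4 + 1 / 9
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1, e2 = c1 / a1, c2 / (a1**2 + a2)
        expected = (k_hat - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
        assert tajimas_d(codes) == pytest.approx(expected, rel=1e-12)

    def test_no_segregating_sites_is_nan(self):
        codes = np.vstack([seq_to_codes("AAAA")] * 5)
        assert math.isnan(tajimas_d(codes))

    def test_missing_sites_dropped_for_s(self):
        codes = np.vstack([
            seq_to_codes("AAAA"),
            seq_to_codes("ATAN"),  # second site segregates; last site uncallable
            seq_to_codes("ATAA"),
            seq_to_codes("AAAA"),
        ])
        assert np.isfinite(tajimas_d(codes))


class TestFst:
    def test_fixed_difference_gives_one(self, two_region_popmap):
        inds = two_region_popmap.individuals
        n = len(inds)
        geno = np.zeros((3, n, 2), np.int8)
        geno[:, 4:, :] = 2
        cat = build_catalog([geno], inds, two_region_popmap)
        assert wc_fst(cat, "A", "B") == pytest.approx(1.0)

    def test_equal_frequencies_near_zero(self, two_region_popmap):
        inds = two_region_popmap.individuals
        n = len(inds)
        geno = np.zeros((3, n, 2), np.int8)
        geno[:, ::2, 0] = 2  # identical allele and genotype frequencies
        cat = build_catalog([geno], inds, two_region_popmap)
        assert abs(wc_fst(cat, "A", "B")) < 0.15

    def test_two_locus_counts_match_naive_transcription(self, two_region_popmap):
        inds = two_region_popmap.individuals
        nind = len(inds)
        rng = np.random.default_rng(5)
        geno = rng.integers(0, 2, size=(2, nind, 2)).astype(np.int8) * 2
        cat = build_catalog([geno[:1], geno[1:]], inds, two_region_popmap)

        # naive scalar Weir-Cockerham (1984), summed over sites and alleles
        num = den = 0.0
        r = 2
        for s in range(2):
            ga, gb = geno[s, :4], geno[s, 4:]
            na, nb = 4.0, 4.0
            nbar = (na + nb) / r
            nc = (r * nbar - (na**2 + nb**2) / (r * nbar)) / (r - 1)
            for allele in (0, 2):
                pa = np.sum(ga == allele) / (2 * na)
                pb = np.sum(gb == allele) / (2 * nb)
                pbar = (na * pa + nb * pb) / (r * nbar)
                s2 = (na * (pa - pbar) ** 2 + nb * (pb - pbar) ** 2) / ((r - 1) * nbar)
                ha = np.sum((ga[:, 0] != ga[:, 1]) & np.any(ga == allele, axis=1))
                hb = np.sum((gb[:, 0] != gb[:, 1]) & np.any(gb == allele, axis=1))
                hbar = (ha + hb) / (r * nbar)
                a = (nbar / nc) * (
                    s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
                )
                b = (nbar / (nbar - 1)) * (
                    pbar * (1 - pbar) - (r - 1) / r * s2
                    - (2 * nbar - 1) / (4 * nbar) * hbar
                )
                c = hbar / 2
                num += a
                den += a + b + c
        assert wc_fst(cat, "A", "B") == pytest.approx(num / den, rel=1e-12)

    def test_label_swap_invariance(self, two_region_popmap):
        inds = two_region_popmap.individuals
        rng = np.random.default_rng(11)
        geno = (rng.integers(0, 2, size=(4, len(inds), 2)) * 2).astype(np.int8)
        cat = build_catalog([geno], inds, two_region_popmap)
        assert wc_fst(cat, "A", "B") == pytest.approx(wc_fst(cat, "B", "A"))

    def test_monomorphic_is_nan(self, two_region_popmap):
        inds = two_region_popmap.individuals
        geno = np.zeros((2, len(inds), 2), np.int8)
        cat = build_catalog([geno], inds, two_region_popmap)
        assert math.isnan(wc_fst(cat, "A", "B"))

    def test_hudson_haplotype_extremes(self):
        same = np.zeros((3, 5), np.int8)
        other = np.full((3, 5), 2, np.int8)
        assert hudson_fst(same, other, unit="haplotype") == pytest.approx(1.0)
        mixed = np.vstack([same[0], other[0], same[0]]).astype(np.int8)
        val = hudson_fst(mixed, mixed.copy(), unit="haplotype")
        assert val == pytest.approx(0.0, abs=1e-9) or val < 0


class TestSummaryVector:
    def test_length_for_four_regions(self):
        from radscape.scenarios import scenario_library
        from radscape.simulate import SampleDesign, simulate_marker

        design = SampleDesign(marker="rad",
                              samples={"BF": 4, "MC": 4, "PY": 4, "CM": 4},
                              n_loci=20, mutation_rate=1e-6)
        cat = simulate_marker(scenario_library()["scenario_17"], design, 3)
        vec = summary_stats(cat)
        assert len(vec) == 4 * 4 + 6 * 3

    def test_region_label_order_is_stable(self, two_region_popmap):
        inds = two_region_popmap.individuals
        geno = (np.random.default_rng(0).integers(0, 2, size=(6, len(inds), 2)) * 2).astype(np.int8)
        cat = build_catalog([geno], inds, two_region_popmap)
        vec = summary_stats(cat)
        assert vec.names[0].startswith("A:") and vec.names[4].startswith("B:")
        assert vec.names[-1] == "A-B:fst"


class TestStrictClock:
    @pytest.mark.parametrize("pct,expected", [(3.54, 1.0), (0.0, 0.0), (1.77, 0.5)])
    def test_linear_conversion(self, pct, expected):
        assert strict_clock_time(pct) == pytest.approx(expected)

    def test_bad_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            strict_clock_time(1.0, rate_percent_per_my=0.0)
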