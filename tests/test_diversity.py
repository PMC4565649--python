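"""Mutant-class mathematics, unique-species counting and the degenerate-
codon comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trimerlib.diversity import (
    FrameshiftModel,
    binomial_classes,
    degenerate_codon_stats,
    frameshift_free_probability,
    poisson_binomial_pmf,
    practical_diversity,
    theoretical_diversity,
    unique_species,
    wildtype_frequency,
)


class TestBinomialClasses:
    def test_zero_class_probability_at_028(self):
        stats = binomial_classes(26, 0.28, 1e8)
        assert stats.P_k[0] == pytest.approx((1 - 0.28) ** 26)
        assert stats.P_k[0] == pytest.approx(1.95e-4, rel=5e-3)

    def test_single_exchange_species_count(self):
        stats = binomial_classes(26, 0.28, 1e8, m=18)
        assert stats.N_k[1] == 26 * 18 == 468

    def test_no_randomization_concentrates_class_zero(self):
        stats = binomial_classes(26, 0.0, 1e8)
        assert stats.P_k[0] == 1.0
        assert np.all(stats.P_k[1:] == 0)

    def test_invariants_hold(self):
        stats = binomial_classes(10, 0.3, 1e6, m=4)
        assert np.isclose(stats.P_k.sum(), 1.0)
        assert np.isclose(stats.L_k.sum(), 1e6)
        assert np.allclose(stats.C_k, stats.F_k * 1e6)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            binomial_classes(26, 1.5, 1e8)
        with pytest.raises(ValueError):
            binomial_classes(26, 0.3, 0)

    def test_poisson_binomial_matches_binomial_for_equal_p(self):
        pmf = poisson_binomial_pmf(np.full(12, 0.28))
        stats = binomial_classes(12, 0.28, 1.0)
        assert np.allclose(pmf, stats.P_k)


class TestUniqueSpecies:
    def test_tiny_library_by_hand(self):
        # n=2, m=2, p=0.5, L=4: classes contribute 1 + 2 + 1
        stats = binomial_classes(2, 0.5, 4, m=2)
        assert unique_species(stats) == pytest.approx(4.0)

    def test_saturation_limit_is_full_theoretical_diversity(self):
        stats = binomial_classes(3, 0.5, 1e12, m=2)
        assert unique_species(stats) == pytest.approx(
            sum(math.comb(3, k) * 2**k for k in range(4))
        )

    def test_monotone_in_library_size(self):
        sizes = [1e3, 1e5, 1e7, 1e9]
        values = [
            unique_species(binomial_classes(6, 0.3, L, m=4)) for L in sizes
        ]
        assert values == sorted(values)

    def test_monotone_in_exchange_probability_below_half(self):
        ps = [0.1, 0.2, 0.3, 0.4, 0.5]
        values = [
            unique_species(binomial_classes(6, p, 1e5, m=4)) for p in ps
        ]
        assert values == sorted(values)

    @pytest.mark.parametrize("p", [0.27, 0.275, 0.28])
    def test_published_l26_diversity_reproduced(self, p):
        stats = binomial_classes(26, p, 1.8e8, m=18)
        corrected = 0.5 * unique_species(stats)
        assert round(corrected / 1e8, 2) == 0.89

    @pytest.mark.parametrize("p", [0.27, 0.275, 0.28])
    def test_published_l24_diversity_reproduced(self, p):
        stats = binomial_classes(24, p, 1.2e6, m=18)
        corrected = 0.5 * unique_species(stats)
        assert round(corrected / 1e6, 1) == 0.6

    def test_expected_distinct_matches_monte_carlo(self):
        rng = np.random.default_rng(0)
        n, m, p, L = 5, 3, 0.3, 30000
        ks = rng.binomial(n, p, size=L)
        seen = set()
        for k in ks:
            Nk = math.comb(n, k) * m**k
            seen.add((int(k), int(rng.integers(0, Nk))))
        stats = binomial_classes(n, p, L, m=m)
        S = unique_species(stats, method="expected_distinct")
        assert abs(S - len(seen)) / len(seen) < 0.02


class TestFrameshift:
    def test_default_model_rounds_to_one_half(self):
        P = frameshift_free_probability()
        assert P == pytest.approx((1 - 0.0026) ** 236 * (1 - 0.0054) ** 24)
        assert round(P, 1) == 0.5

    def test_zero_rates_give_certainty(self):
        m = FrameshiftModel(236, 0.0, 24, 0.0)
        assert frameshift_free_probability(m) == 1.0

    def test_certain_frameshift_gives_zero(self):
        m = FrameshiftModel(236, 1.0, 24, 0.0054)
        assert frameshift_free_probability(m) == 0.0

    def test_multiplicative_over_gene_partitions(self):
        whole = frameshift_free_probability(FrameshiftModel(236, 0.0026, 24, 0.0054))
        part1 = frameshift_free_probability(FrameshiftModel(100, 0.0026, 10, 0.0054))
        part2 = frameshift_free_probability(FrameshiftModel(136, 0.0026, 14, 0.0054))
        assert whole == pytest.approx(part1 * part2)


class TestDegenerateCodons:
    def test_nns_redundancy_over_26_positions(self):
        d = degenerate_codon_stats("NNS", 26)
        assert d["ratio"] == pytest.approx((32 / 20) ** 26)
        assert float(f"{d['ratio']:.0e}") == 2e5  # one significant figure

    def test_nnk_single_position(self):
        d = degenerate_codon_stats("NNK", 1)
        assert d["gene_count"] == 32
        assert d["protein_count"] == 20
        assert d["stop_codons_per_position"] == 1

    def test_nnn_single_position(self):
        d = degenerate_codon_stats("NNN", 1)
        assert d["gene_count"] == 64
        assert d["stop_codons_per_position"] == 3

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            degenerate_codon_stats("NDT", 4)


class TestPracticalDiversity:
    def test_published_gene_protein_ratio(self):
        stats = binomial_classes(26, 0.27, 1.8e8, m=18)
        S = 0.5 * unique_species(stats)
        # both quantities reported to two significant figures
        genes = round(0.5 * 1.8e8 / 1e7) * 1e7
        assert round(genes / (round(S / 1e6) * 1e6), 2) == 1.01

    def test_identity_fraction(self):
        pdiv = practical_diversity(1e6, 1.0)
        assert pdiv.frameshift_free_genes == 1e6

    def test_small_library_by_hand(self):
        pdiv = practical_diversity(1.2e6, 0.5)
        assert pdiv.frameshift_free_genes == pytest.approx(6e5)


class TestWildtypeFrequency:
    def test_published_value(self):
        f = wildtype_frequency(26, 0.27, frameshift_free_fraction=0.5)
        assert float(f"{f:.1e}") == pytest.approx(1.4e-4)

    def test_no_randomization_gives_unity(self):
        assert wildtype_frequency(26, 0.0) == 1.0

    def test_million_transformants_yield_over_100_wild_types(self):
        f = wildtype_frequency(26, 0.27, frameshift_free_fraction=0.5)
        assert f * 1e6 > 100


class TestTheoreticalDiversity:
    def test_published_values(self):
        assert theoretical_diversity(8) == pytest.approx(1.7e10, rel=0.02)
        assert theoretical_diversity(5) == 2476099 == pytest.approx(2.5e6, rel=0.02)

    def test_zero_positions(self):
        assert theoretical_diversity(0) == 1.0

    @given(k=st.integers(min_value=0, max_value=12))
    @settings(derandomize=True, max_examples=13)
    def test_multiplicative_growth(self, k):
        assert theoretical_diversity(k + 1) == pytest.approx(
            19 * theoretical_diversity(k)
        )
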