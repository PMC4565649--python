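"""Trimer mixture composition, incorporation probabilities and exchange
statistics."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trimerlib.mixtures import (
    MixtureEntry,
    MixtureSourceTable,
    RandomizationScheme,
    SchemePosition,
    StandardMixture,
    apply_coupling_corrections,
    build_standard_mixture,
    exchange_probabilities,
    position_mixture,
)


class TestStandardMixture:
    def test_packaged_mixture_has_19_entries_summing_to_one(self, mixture):
        assert len(mixture.entries) == 19
        assert "C" in mixture.excluded_residues
        assert math.isclose(
            sum(e.protein_fraction for e in mixture.entries), 1.0, abs_tol=1e-9
        )

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            StandardMixture(
                entries=(
                    MixtureEntry("A", "GCT", 0.6),
                    MixtureEntry("G", "GGT", 0.3),
                )
            )

    def test_duplicate_residue_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            StandardMixture(
                entries=(
                    MixtureEntry("A", "GCT", 0.5),
                    MixtureEntry("A", "GCA", 0.5),
                )
            )


class TestBuildStandardMixture:
    def test_degenerate_weighting_returns_normalized_surface(self):
        surface = {"A": 0.3, "G": 0.3, "C": 0.2, "W": 0.2}
        catalytic = {"A": 1.0}
        table = MixtureSourceTable(surface, catalytic, weights=(1.0, 0.0))
        mix = build_standard_mixture(table, excluded={"C"})
        # C removed, remainder renormalized: 0.3/0.8, 0.3/0.8, 0.2/0.8
        assert mix.fraction("A") == pytest.approx(0.375)
        assert mix.fraction("G") == pytest.approx(0.375)
        assert mix.fraction("W") == pytest.approx(0.25)
        assert mix.fraction("C") == 0.0

    def test_uniform_sources_give_uniform_19_mixture(self):
        uniform = {aa: 1 / 20 for aa in "ACDEFGHIKLMNPQRSTVWY"}
        mix = build_standard_mixture(
            MixtureSourceTable(uniform, uniform), excluded={"C"}
        )
        for e in mix.entries:
            assert e.protein_fraction == pytest.approx(1 / 19)

    def test_two_residue_blend_by_hand(self):
        table = MixtureSourceTable({"A": 0.6, "G": 0.4}, {"A": 0.6, "G": 0.4})
        mix = build_standard_mixture(table, excluded=set())
        assert mix.fraction("A") == pytest.approx(0.6)
        assert mix.fraction("G") == pytest.approx(0.4)

    def test_negative_frequency_names_the_residue(self):
        with pytest.raises(ValueError, match="W"):
            MixtureSourceTable({"A": 1.1, "W": -0.1}, {"A": 1.0})

    def test_empty_included_set_rejected(self):
        table = MixtureSourceTable({"A": 1.0}, {"A": 1.0})
        with pytest.raises(ValueError, match="exclusion"):
            build_standard_mixture(table, excluded={"A"})

    @given(scale=st.floats(min_value=0.01, max_value=100.0))
    @settings(derandomize=True, max_examples=25)
    def test_scale_invariance(self, scale):
        surface = {"A": 3.0, "G": 2.0, "W": 1.0}
        catalytic = {"A": 1.0, "G": 4.0}
        base = build_standard_mixture(
            MixtureSourceTable(surface, catalytic), excluded=set()
        )
        scaled = build_standard_mixture(
            MixtureSourceTable(
                {k: v * scale for k, v in surface.items()},
                {k: v * scale for k, v in catalytic.items()},
            ),
            excluded=set(),
        )
        for aa in surface:
            assert scaled.fraction(aa) == pytest.approx(base.fraction(aa))


class TestPositionMixture:
    def test_resident_lysine_probability_by_hand(self, scheme):
        # K179, f_K = 0.101: P(AAA) = 0.7 + 0.3 * 0.101
        pm = position_mixture(scheme, 179)
        assert pm["AAA"] == pytest.approx(0.7303)
        assert sum(v for c, v in pm.items() if c != "AAA") == pytest.approx(0.2697)

    def test_resident_glycine_probability_by_hand(self, scheme):
        pm = position_mixture(scheme, 80)
        assert pm["GGT"] == pytest.approx(0.7213)

    def test_no_randomization_degenerate_case(self, mixture):
        scheme = RandomizationScheme(
            positions=(SchemePosition(1, "AAA", "K"),),
            mixture=mixture,
            resident_fraction=1.0,
            mixture_fraction=0.0,
        )
        pm = position_mixture(scheme, 1)
        assert pm["AAA"] == pytest.approx(1.0)
        assert all(v == 0 for c, v in pm.items() if c != "AAA")

    def test_probabilities_sum_to_one_at_every_position(self, scheme):
        for p in scheme.protein_positions:
            assert abs(sum(position_mixture(scheme, p).values()) - 1.0) < 1e-12

    def test_unknown_position_rejected(self, scheme):
        with pytest.raises(KeyError):
            position_mixture(scheme, 9)


class TestExchangeProbabilities:
    def test_full_scheme_expected_exchanges(self, scheme):
        _, mean, total = exchange_probabilities(scheme)
        assert round(total, 2) == 7.31
        assert round(mean, 2) == 0.28

    def test_per_position_values_bounded_by_mixture_fraction(self, scheme):
        per_pos, _, _ = exchange_probabilities(scheme)
        assert all(0 <= p <= scheme.mixture_fraction for p in per_pos)

    def test_resident_absent_from_mixture_gives_full_mixture_fraction(self, mixture):
        # cysteine resident: f_C = 0, so p = 0.3 exactly
        scheme = RandomizationScheme(
            positions=(SchemePosition(1, "TGC", "C"),), mixture=mixture
        )
        per_pos, _, _ = exchange_probabilities(scheme)
        assert per_pos == [pytest.approx(0.3)]

    def test_empty_scheme_rejected(self, mixture):
        scheme = RandomizationScheme(positions=(), mixture=mixture)
        with pytest.raises(ValueError):
            exchange_probabilities(scheme)


class TestCouplingCorrections:
    def test_tryptophan_amount_by_hand(self, mixture):
        amounts = apply_coupling_corrections(mixture)
        assert amounts["TGG"] == pytest.approx(0.007 * 2.4)

    def test_identity_corrections_return_fractions(self):
        mix = StandardMixture(
            entries=(
                MixtureEntry("A", "GCT", 0.5, 1.0),
                MixtureEntry("G", "GGT", 0.5, 1.0),
            )
        )
        assert apply_coupling_corrections(mix) == {"GCT": 0.5, "GGT": 0.5}

    def test_renormalized_two_entry_mixture_by_hand(self):
        mix = StandardMixture(
            entries=(
                MixtureEntry("A", "GCT", 0.5, 2.0),
                MixtureEntry("G", "GGT", 0.5, 1.0),
            )
        )
        amounts = apply_coupling_corrections(mix, renormalize=True)
        assert amounts["GCT"] == pytest.approx(2 / 3)
        assert amounts["GGT"] == pytest.approx(1 / 3)

    def test_nonpositive_correction_rejected(self):
        with pytest.raises(ValueError, match="coupling"):
            StandardMixture(entries=(MixtureEntry("A", "GCT", 1.0, -1.0),))
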