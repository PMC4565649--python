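"""Mutation calling, deletion classification, report tables and summary
statistics."""

import numpy as np
import pytest

from trimerlib.analyzer import (
    call_mutations,
    classify_deletions,
    musi_reports,
    parse_aligned_set,
    summary_statistics,
)

REF = "ATGGCTAAA"
MASK = "...***..."  # codon 2 targeted


def _set(targets, mask=MASK, ref=REF):
    return parse_aligned_set(ref, mask, targets)


class TestParseAlignedSet:
    def test_valid_set_accepted(self):
        cset = _set([("c1", "ATGGCTAAA"), ("c2", "ATGCATAAA")])
        assert cset.site_directed
        assert cset.targeted_codons() == [2]

    def test_unequal_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            _set([("c1", "ATGGCTAA")])

    def test_mask_not_codon_aligned_rejected(self):
        with pytest.raises(ValueError, match="codon"):
            _set([("c1", REF)], mask="....**...")

    def test_strict_mode_enforces_250_target_limit(self):
        targets = [(f"c{i}", REF) for i in range(251)]
        with pytest.raises(ValueError, match="250"):
            parse_aligned_set(REF, MASK, targets, strict_musi=True)
        with pytest.warns(UserWarning, match="250"):
            parse_aligned_set(REF, MASK, targets, strict_musi=False)


class TestCallMutations:
    def test_codon_substitution_yields_codon_and_aa_records(self):
        recs = call_mutations(_set([("c1", "ATGCATAAA")]))
        codon = [r for r in recs if r.level == "codon"]
        aa = [r for r in recs if r.level == "amino_acid"]
        assert len(codon) == 1
        assert (codon[0].ref_state, codon[0].obs_state) == ("GCT", "CAT")
        assert codon[0].in_targeted_codon
        assert len(aa) == 1
        assert (aa[0].ref_state, aa[0].obs_state, aa[0].position) == ("A", "H", 2)

    def test_whole_codon_gap_is_a_triple_deletion(self):
        recs = call_mutations(_set([("c1", "ATG---AAA")]))
        dels = [r for r in recs if r.event_class == "deletion_3"]
        assert len(dels) == 1
        assert dels[0].position == 4
        assert dels[0].in_targeted_codon
        assert not [r for r in recs if r.level == "codon"]

    def test_single_gap_is_a_single_deletion(self):
        recs = call_mutations(_set([("c1", "ATGGC-AAA")]))
        dels = [r for r in recs if r.event_class == "deletion_1"]
        assert len(dels) == 1
        assert dels[0].position == 6

    def test_silent_codon_change_has_no_amino_acid_record(self):
        recs = call_mutations(_set([("c1", "ATGGCCAAA")]))  # GCT->GCC, still Ala
        assert [r.level for r in recs if r.level != "nucleotide"] == ["codon"]

    def test_ambiguous_base_flags_instead_of_aborting(self):
        recs = call_mutations(_set([("c1", "ATGGNTAAA")]))
        assert all(r.flagged for r in recs)

    def test_insertion_reported_at_nucleotide_level_only(self):
        cset = parse_aligned_set(
            "ATG-GCTAAA", "....***...", [("c1", "ATGCGCTAAA")]
        )
        recs = call_mutations(cset)
        ins = [r for r in recs if r.event_class == "insertion"]
        assert len(ins) == 1 and ins[0].obs_state == "C"
        assert not [r for r in recs if r.level in ("codon", "amino_acid")]


class TestClassifyDeletions:
    def test_rates_per_triplet_inside_and_per_nucleotide_outside(self):
        cset = _set(
            [
                ("c1", "ATG---AAA"),
                ("c2", "AT-GCTAAA"),
                ("c3", "ATGGCTAAA"),
            ]
        )
        stats = classify_deletions(call_mutations(cset), cset)
        assert stats.counts_inside["deletion_3"] == 1
        assert stats.counts_outside["deletion_1"] == 1
        assert stats.triplets_inside == 3  # 3 clones x 1 targeted codon
        assert stats.nucleotides_outside == 18  # 3 clones x 6 nt
        assert stats.rate_inside(3) == pytest.approx(1 / 3)
        assert stats.rate_outside(1) == pytest.approx(1 / 18)

    def test_zero_events_give_zero_rates(self):
        cset = _set([("c1", REF)])
        stats = classify_deletions(call_mutations(cset), cset)
        assert all(v == 0 for v in stats.counts_inside.values())
        assert all(v == 0 for v in stats.counts_outside.values())

    def test_run_of_four_is_anomalous_and_excluded(self):
        cset = parse_aligned_set(
            "ATGGCTAAACGT", "...***......", [("c1", "ATGGCT----GT")]
        )
        stats = classify_deletions(call_mutations(cset), cset)
        assert stats.anomalous_runs == 1
        assert all(v == 0 for v in stats.counts_inside.values())
        assert all(v == 0 for v in stats.counts_outside.values())


class TestReports:
    def test_two_substitutions_give_sheet4_grand_total_two(self):
        cset = _set([("c1", "ATGCATAAA"), ("c2", "ATGGGTAAA")])
        bundle = musi_reports(cset, call_mutations(cset))
        assert bundle.sheet4_substitution_matrix.loc["total", "total"] == 2
        assert bundle.sheet4_substitution_matrix.loc["pos2", "H"] == 1
        assert bundle.sheet4_substitution_matrix.loc["pos2", "G"] == 1

    def test_transition_outside_mask_counted_in_sheet5(self):
        cset = _set([("c1", "ATAGCTAAA")])  # G>A at nt 3, outside mask
        bundle = musi_reports(cset, call_mutations(cset))
        s5 = bundle.sheet5_titv
        assert s5.loc[s5["class"] == "transition", "count"].sum() == 1
        assert s5.loc[s5["class"] == "transversion", "count"].sum() == 0

    def test_clean_alignment_gives_empty_sheets(self):
        cset = _set([("c1", REF), ("c2", REF)])
        bundle = musi_reports(cset, call_mutations(cset))
        assert bundle.sheet1_nt.empty
        assert bundle.sheet2_codon.empty
        assert bundle.sheet4_substitution_matrix.loc["total", "total"] == 0
        assert bundle.sheet5_titv["count"].sum() == 0

    def test_sheet_totals_match_simulator_ground_truth(self, clean_clones):
        cset, truth = clean_clones
        records = call_mutations(cset)
        bundle = musi_reports(cset, records)
        total = bundle.sheet4_substitution_matrix.loc["total", "total"]
        assert total == len(truth.codon_exchanges)


class TestSummaryStatistics:
    def test_all_wild_type_clones_have_zero_rates(self, scheme, cds):
        mask = "".join(
            "*" if (i // 3 + 1) in set(scheme.protein_positions) else "."
            for i in range(len(cds))
        )
        cset = parse_aligned_set(cds, mask, [("c1", cds), ("c2", cds)])
        summary = summary_statistics(cset, call_mutations(cset), scheme)
        assert summary.overall_rate == 0
        assert (summary.per_position["observed_rate"] == 0).all()
        hist = summary.class_histogram
        assert hist.loc[hist["k"] == 0, "observed"].item() == 2

    def test_count_conservation_across_outputs(self, clean_clones, scheme):
        cset, _ = clean_clones
        records = call_mutations(cset)
        bundle = musi_reports(cset, records)
        summary = summary_statistics(cset, records, scheme)
        sheet4_total = bundle.sheet4_substitution_matrix.loc["total", "total"]
        hist = summary.class_histogram
        weighted = int((hist["k"] * hist["observed"]).sum())
        assert sheet4_total == summary.n_exchanges == weighted

    def test_rates_invariant_under_target_reordering(self, clean_clones, scheme):
        cset, _ = clean_clones
        base = summary_statistics(cset, call_mutations(cset), scheme)
        from trimerlib.analyzer import AlignedCloneSet

        reordered = AlignedCloneSet(
            reference=cset.reference,
            mask=cset.mask,
            targets=tuple(reversed(cset.targets)),
        )
        again = summary_statistics(reordered, call_mutations(reordered), scheme)
        assert np.allclose(
            base.per_position["observed_rate"], again.per_position["observed_rate"]
        )
        assert base.overall_rate == again.overall_rate

    def test_per_residue_rates_recover_configured_probabilities(
        self, clean_clones, scheme
    ):
        cset, _ = clean_clones
        summary = summary_statistics(cset, call_mutations(cset), scheme)
        for _, row in summary.per_residue.iterrows():
            p = row["expected_rate"]
            se = np.sqrt(p * (1 - p) / row["n_codons"])
            assert abs(row["observed_rate"] - p) <= 3 * se + 1e-12

    def test_zero_clones_rejected(self, scheme, cds):
        cset = parse_aligned_set(cds, "*" * 0 + "." * len(cds), [])
        with pytest.raises(ValueError, match="clones|mask"):
            summary_statistics(cset, [], scheme)
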