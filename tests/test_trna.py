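"""Cloverleaf parsing, canonical numbering, mutations, extinction."""

import pytest

from nsun6kit.synth import ScaffoldConstraints, generate_scaffold, scaffold_layout
from nsun6kit.trna import (
    MONOMER_EPSILON_260,
    AlphabetError,
    CloverleafParseError,
    TRNAError,
    TRNARecord,
    apply_pair_swap,
    apply_point_mutation,
    delete_cca,
    element_profile,
    extinction_coefficient_260,
    pair_kind,
    parse_cloverleaf,
)


class TestRecordValidation:
    def test_normalizes_dna_alphabet_and_case(self):
        rec = TRNARecord("x", "acgt" * 16)
        assert set(rec.sequence) == {"A", "C", "G", "U"}
        assert "T" not in rec.sequence

    def test_rejects_non_rna_residues(self):
        with pytest.raises(AlphabetError):
            TRNARecord("x", "ACGX" * 16)

    @pytest.mark.parametrize("length", [59, 101])
    def test_rejects_out_of_range_length(self, length):
        with pytest.raises(TRNAError):
            TRNARecord("x", "A" * length)


class TestParseCloverleaf:
    def test_wild_type_profile_matches_constraints(self, thr_cgu):
        profile = element_profile(thr_cgu)
        assert profile.n72 == "C"
        assert profile.n73 == "U"
        assert profile.pair_2_71 == ("C", "G")
        assert profile.pair_3_70 == ("C", "G")
        assert profile.pair_11_24 == ("C", "G")
        assert profile.pair_12_23 == ("C", "G")
        assert profile.cca_present is True

    def test_arm_spans_disjoint_ordered_and_cover_sequence(self, thr_cgu):
        spans = list(thr_cgu.arm_spans.values())
        assert all(a < b for a, b in spans)
        flat = [i for a, b in spans for i in range(a, b)]
        assert flat == list(range(len(thr_cgu.sequence)))

    def test_position_map_is_injective(self, thr_cgu):
        indices = list(thr_cgu.position_map.values())
        assert len(indices) == len(set(indices))

    def test_acceptor_stem_pairs_canonical_1_7_with_66_72(self, thr_cgu):
        acceptor = [p for p in thr_cgu.pairs if p.pos5 <= 7]
        assert [(p.pos5, p.pos3) for p in acceptor] == [
            (k, 73 - k) for k in range(1, 8)
        ]

    def test_cca_deletion_keeps_former_discriminator_at_73(self, thr_cgu):
        trimmed = TRNARecord("x", thr_cgu.sequence[:-3])
        ann = parse_cloverleaf(trimmed)
        assert ann.cca_present is False
        assert ann.residue(73) == thr_cgu.residue(73)
        assert 74 not in ann.position_map

    def test_pairs_match_brute_force_over_known_stem_indices(self):
        """For seeded scaffolds, parser pairs equal an exhaustive
        complementarity check over the generator's designed indices."""
        for seed in range(50):
            long_arm = seed % 2 == 1
            cons = ScaffoldConstraints(seed=seed, long_variable_arm=long_arm)
            rec = generate_scaffold(cons)
            ann = parse_cloverleaf(rec)
            layout = scaffold_layout(long_arm, cca=True)
            expected = sorted(
                idx_pair
                for stem in layout["pairs"].values()
                for idx_pair in stem
            )
            observed = sorted(
                (ann.position_map[p.pos5], ann.position_map[p.pos3])
                for p in ann.pairs
            )
            assert observed == expected
            for p in ann.pairs:  # kind recomputed independently
                i5, i3 = ann.position_map[p.pos5], ann.position_map[p.pos3]
                assert p.kind == pair_kind(rec.sequence[i5], rec.sequence[i3])

    def test_determinism(self, thr_cgu_record):
        assert parse_cloverleaf(thr_cgu_record) == parse_cloverleaf(thr_cgu_record)

    def test_broken_acceptor_stem_fails(self):
        # poly-A 5' end cannot pair the GC-rich acceptor 3' strand
        rec = TRNARecord("x", "A" * 40 + "G" * 20 + "GGGGCCC" + "U" + "CCA")
        with pytest.raises(CloverleafParseError):
            parse_cloverleaf(rec)

    def test_json_export_round_trips_key_fields(self, thr_cgu):
        import json

        payload = json.loads(thr_cgu.to_json())
        assert payload["sequence"] == thr_cgu.sequence
        assert payload["cca_present"] is True
        assert payload["position_map"]["73"] == thr_cgu.position_map[73]


class TestMutations:
    def test_point_mutation_changes_exactly_one_residue(self, thr_cgu):
        mutated = apply_point_mutation(thr_cgu, 73, "G")
        diffs = [
            i
            for i, (a, b) in enumerate(zip(thr_cgu.sequence, mutated.sequence))
            if a != b
        ]
        assert diffs == [thr_cgu.position_map[73]]
        assert element_profile(mutated).n73 == "G"

    def test_identity_mutation_is_noop(self, thr_cgu):
        assert apply_point_mutation(thr_cgu, 73, "U").sequence == thr_cgu.sequence

    def test_mutation_involution_restores_sequence(self, thr_cgu):
        once = apply_point_mutation(thr_cgu, 72, "A")
        back = apply_point_mutation(once, 72, "C")
        assert back.sequence == thr_cgu.sequence

    def test_unknown_position_raises(self, thr_cgu):
        with pytest.raises(TRNAError):
            apply_point_mutation(thr_cgu, 77, "A")

    def test_pair_swap_updates_both_residues_and_kind(self, thr_cgu):
        swapped = apply_pair_swap(thr_cgu, 2, 71, "G", "C")
        assert element_profile(swapped).pair_2_71 == ("G", "C")
        assert swapped.pair_at(2, 71).kind == "watson-crick"
        wobbled = apply_pair_swap(thr_cgu, 12, 23, "U", "G")
        assert wobbled.pair_at(12, 23).kind == "wobble"

    def test_pair_swap_rejects_non_pair(self, thr_cgu):
        with pytest.raises(TRNAError):
            apply_pair_swap(thr_cgu, 2, 70, "G", "C")

    def test_delete_cca_then_append_restores(self, thr_cgu):
        deleted = delete_cca(thr_cgu)
        assert deleted.cca_present is False
        assert len(deleted.sequence) == len(thr_cgu.sequence) - 3
        assert deleted.sequence + "CCA" == thr_cgu.sequence

    def test_delete_cca_changes_only_cca_flag_in_profile(self, thr_cgu):
        before = element_profile(thr_cgu)
        after = element_profile(delete_cca(thr_cgu))
        assert after.cca_present is False
        for field in ("n72", "n73", "pair_2_71", "pair_3_70", "pair_11_24", "pair_12_23"):
            assert getattr(after, field) == getattr(before, field)

    def test_delete_cca_requires_cca(self, thr_cgu):
        with pytest.raises(TRNAError):
            delete_cca(delete_cca(thr_cgu))


class TestExtinctionCoefficient:
    def test_single_monomers_sum(self):
        assert extinction_coefficient_260("ACGU") == pytest.approx(
            sum(MONOMER_EPSILON_260.values())
        )

    def test_additive_over_concatenation(self):
        seq = "GGCAUCGUA"
        assert extinction_coefficient_260(seq * 2) == pytest.approx(
            2 * extinction_coefficient_260(seq)
        )

    def test_matches_per_residue_summation_on_scaffold(self, thr_cgu_record):
        brute = sum(MONOMER_EPSILON_260[b] for b in thr_cgu_record.sequence)
        assert extinction_coefficient_260(thr_cgu_record) == pytest.approx(brute)
        assert extinction_coefficient_260(thr_cgu_record) > 0

    def test_alphabet_error(self):
        with pytest.raises(AlphabetError):
            extinction_coefficient_260("ACGN")


@pytest.mark.parametrize(
    "bases,kind",
    [
        (("A", "U"), "watson-crick"),
        (("G", "C"), "watson-crick"),
        (("G", "U"), "wobble"),
        (("U", "G"), "wobble"),
        (("A", "G"), "mismatch"),
        (("C", "C"), "mismatch"),
    ],
)
def test_pair_kind_classification(bases, kind):
    assert pair_kind(*bases) == kind
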