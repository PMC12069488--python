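import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from isomirkit.caller import (
    AssignmentPolicy,
    CollapsedRead,
    IsomirCall,
    Unassigned,
    VariantClass,
    assign_read,
    build_display_name,
    classify,
    classify_reads,
    collapse_tsv,
    parse_display_name,
    split_templated_tail,
)
from isomirkit.reference import HairpinRecord, MatureAnnotation, build_index

from conftest import TOY_MATURE


class TestClassifyDecision:
    @pytest.mark.parametrize(
        "d5, d3, nta, subs, expected",
        [
            (0, 0, "", (), VariantClass.Canonical),
            (-1, 0, "", (), VariantClass.Ext5p),
            (2, 0, "", (), VariantClass.Trim5p),
            (0, -2, "", (), VariantClass.Trim3p),
            (0, 1, "", (), VariantClass.Ext3p),
            (0, 0, "U", (), VariantClass.NTA),
            (0, 2, "U", (), VariantClass.NTA),  # tail dominates mixed 3' calls
            (0, -1, "AA", (), VariantClass.NTA),
            (0, 0, "", ((5, "G", "A"),), VariantClass.NucVar),
            (-1, -2, "", (), VariantClass.MultiVariant),
            (1, 0, "U", (), VariantClass.MultiVariant),
            (0, -1, "", ((3, "C", "U"),), VariantClass.MultiVariant),
        ],
    )
    def test_decision_table(self, d5, d3, nta, subs, expected):
        assert classify(d5, d3, nta, subs) is expected

    def test_canonical_iff_all_zero(self):
        # the biconditional direction not covered by the table
        assert classify(0, 0, "", ()) is VariantClass.Canonical
        for args in [(1, 0, "", ()), (0, 0, "A", ()), (0, 0, "", ((1, "A", "G"),))]:
            assert classify(*args) is not VariantClass.Canonical


class TestTemplatedTailSplit:
    @pytest.mark.parametrize(
        "overhang, context, expected",
        [
            ("GU", "GUA", (2, "")),
            ("GUU", "GUA", (2, "U")),
            ("AA", "", (0, "AA")),
            ("", "GUA", (0, "")),
            ("UUU", "GGG", (0, "UUU")),
        ],
    )
    def test_split(self, overhang, context, expected):
        assert split_templated_tail(overhang, context) == expected


class TestAssignment:
    def test_five_prime_extended_assay_sequence(self, toy_index):
        # the A-prefixed canonical is the +1 5' extension with a shifted seed
        call = assign_read("A" + TOY_MATURE, toy_index)
        assert call.mature_name == "toy-miR-1-5p"
        assert call.variant_class is VariantClass.Ext5p
        assert (call.d5, call.d3, call.nta_tail) == (-1, 0, "")
        assert call.display_name == "isomiR-1-5p-Ext5p(+1)"
        assert not call.seed_conserved

    def test_identical_read_is_canonical(self, toy_index):
        call = assign_read(TOY_MATURE, toy_index)
        assert call.variant_class is VariantClass.Canonical
        assert (call.d5, call.d3) == (0, 0)
        assert call.display_name == "toy-miR-1-5p"
        assert call.seed_conserved

    def test_three_prime_trim(self, toy_index):
        call = assign_read(TOY_MATURE[:-2], toy_index)
        assert call.variant_class is VariantClass.Trim3p
        assert call.d3 == -2
        assert call.display_name == "isomiR-1-5p-Trim3p(-2)"
        assert call.seed_conserved  # 3' change leaves seed positions 2-7

    def test_non_templated_tail(self, toy_index):
        # hairpin context after the mature is "GGAUU": appending U is non-templated
        call = assign_read(TOY_MATURE + "U", toy_index)
        assert call.variant_class is VariantClass.NTA
        assert (call.d3, call.nta_tail) == (0, "U")

    def test_templated_extension(self, toy_index):
        call = assign_read(TOY_MATURE + "GG", toy_index)
        assert call.variant_class is VariantClass.Ext3p
        assert call.d3 == 2

    def test_internal_substitution(self, toy_index):
        mutated = TOY_MATURE[:9] + ("A" if TOY_MATURE[9] != "A" else "C") + TOY_MATURE[10:]
        call = assign_read(mutated, toy_index)
        assert call.variant_class is VariantClass.NucVar
        assert len(call.substitutions) == 1
        pos, ref, alt = call.substitutions[0]
        assert pos == 10 and ref == TOY_MATURE[9]

    def test_two_substitutions_unassigned(self, toy_index):
        mutated = list(TOY_MATURE)
        for i in (5, 12):
            mutated[i] = "A" if mutated[i] != "A" else "C"
        result = assign_read("".join(mutated), toy_index)
        assert isinstance(result, Unassigned) and result.reason == "no_hit"

    def test_length_bounds(self, toy_index):
        assert assign_read(TOY_MATURE[:10], toy_index).reason == "length"

    def test_unrelated_sequence_no_hit(self, toy_index):
        result = assign_read("ACGU" * 5, toy_index)
        assert isinstance(result, Unassigned) and result.reason == "no_hit"

    def test_ambiguous_across_duplicated_matures(self):
        # identical mature on two hairpins: a canonical read ties and is dropped
        hp1 = HairpinRecord("h1", "h1", "GGG" + TOY_MATURE + "ACGUA")
        hp2 = HairpinRecord("h2", "h2", "CCC" + TOY_MATURE + "UUUAC")
        index = build_index(
            [hp1, hp2],
            [
                MatureAnnotation("mir-A-5p", "h1", 3, 3 + len(TOY_MATURE), "5p"),
                MatureAnnotation("mir-B-5p", "h2", 3, 3 + len(TOY_MATURE), "5p"),
            ],
        )
        result = assign_read(TOY_MATURE, index)
        assert isinstance(result, Unassigned) and result.reason == "ambiguous"
        fractional = assign_read(
            TOY_MATURE, index, AssignmentPolicy(multimap="fractional")
        )
        assert isinstance(fractional, list) and len(fractional) == 2
        assert all(call.fraction == 0.5 for call in fractional)

    def test_empty_reference_refused(self, toy_index):
        empty = build_index(list(toy_index.hairpins.values()), [])
        with pytest.raises(ValueError, match="no mature annotations"):
            assign_read(TOY_MATURE, empty)


class TestDisplayNames:
    @pytest.mark.parametrize(
        "mature, d5, d3, nta, subs, expected",
        [
            ("hsa-miR-411-5p", -1, 0, "", (), "isomiR-411-5p-Ext5p(+1)"),
            ("hsa-miR-409-3p", -1, 0, "", (), "isomiR-409-3p-Ext5p(+1)"),
            ("toy-miR-1-5p", 0, -2, "", (), "isomiR-1-5p-Trim3p(-2)"),
            ("hsa-miR-7-5p", 0, -4, "", (), "isomiR-7-5p-Trim3p(-4)"),
            ("hsa-miR-375", 0, 0, "AU", (), "isomiR-375-NTA(+2)"),
            ("hsa-miR-375", 0, 0, "", ((5, "G", "A"),), "isomiR-375-NucVar(5G>A)"),
            ("hsa-miR-375", -1, -2, "", (), "isomiR-375-Ext5p(+1)-Trim3p(-2)"),
        ],
    )
    def test_naming_rule(self, mature, d5, d3, nta, subs, expected):
        call = IsomirCall(
            sequence="A" * 20,
            mature_name=mature,
            variant_class=classify(d5, d3, nta, subs),
            d5=d5,
            d3=d3,
            nta_tail=nta,
            substitutions=subs,
            seed="AAAAAA",
            seed_conserved=False,
            display_name="",
        )
        assert build_display_name(call) == expected

    @given(
        d5=st.integers(-3, 3),
        d3=st.integers(-4, 4),
        nta_len=st.integers(0, 2),
        sub=st.sampled_from([None, (5, "G", "A"), (12, "C", "U")]),
    )
    @settings(derandomize=True, max_examples=200)
    def test_name_round_trip(self, d5, d3, nta_len, sub):
        subs = (sub,) if sub else ()
        nta = "U" * nta_len
        if d3 > 0 and nta:
            d3 = 0  # generator-level: templated ext + tail prints both; keep simple combos valid
        variant_class = classify(d5, d3, nta, subs)
        call = IsomirCall(
            sequence="A" * 22,
            mature_name="hsa-miR-99a-5p",
            variant_class=variant_class,
            d5=d5,
            d3=d3,
            nta_tail=nta,
            substitutions=subs,
            seed="AAAAAA",
            seed_conserved=True,
            display_name="",
        )
        parsed = parse_display_name(build_display_name(call))
        assert parsed["variant_class"] == variant_class
        assert parsed["d5"] == d5
        assert parsed["d3"] == d3
        assert parsed["nta_len"] == len(nta)
        assert parsed["substitutions"] == subs


class TestCallTable:
    def _reads(self, sequences, counts):
        return [
            CollapsedRead(sequence=s, counts=c, sample_ids=("s1", "s2"))
            for s, c in zip(sequences, counts)
        ]

    def test_count_conservation_and_order_invariance(self, toy_index):
        reads = self._reads(
            [TOY_MATURE, "A" + TOY_MATURE, TOY_MATURE[:-2], "ACGU" * 5],
            [(10, 5), (3, 0), (2, 2), (7, 1)],
        )
        calls, unassigned = classify_reads(reads, toy_index)
        for sample, total in [("s1", 22), ("s2", 8)]:
            assert calls[sample].sum() + unassigned[sample].sum() == total
        calls_rev, unassigned_rev = classify_reads(reads[::-1], toy_index)
        pd.testing.assert_frame_equal(calls, calls_rev)
        pd.testing.assert_frame_equal(unassigned, unassigned_rev)

    def test_collapse_tsv_round_trip(self, tmp_path, toy_index):
        path = tmp_path / "reads.tsv"
        pd.DataFrame(
            {
                "sequence": [TOY_MATURE, TOY_MATURE, "A" + TOY_MATURE],
                "sample": ["s1", "s2", "s1"],
                "count": [4, 6, 2],
            }
        ).to_csv(path, sep="\t", index=False)
        reads = collapse_tsv(path)
        assert {r.sequence: r.counts for r in reads} == {
            TOY_MATURE: (4, 6),
            "A" + TOY_MATURE: (2, 0),
        }


class TestTruthRecovery:
    def test_planted_classes_recovered_without_error(self, syn_ref):
        from isomirkit import simulate

        spec = simulate.CompositionSpec(library_size=30_000, n_samples=1, seed=13)
        reads_by_dataset, truth = simulate.generate_reads(spec, syn_ref)
        reads = reads_by_dataset["ds1"]
        calls, unassigned = classify_reads(reads, syn_ref)
        assert unassigned.empty
        merged = calls.merge(truth, on="sequence", suffixes=("", "_truth"))
        assert len(merged) == len(truth)
        assert (merged["variant_class"] == merged["variant_class_truth"]).all()
        assert (merged["d5"] == merged["d5_truth"]).all()
        assert (merged["d3"] == merged["d3_truth"]).all()

    def test_pure_3prime_variants_keep_seed(self, syn_ref):
        from isomirkit import simulate

        spec = simulate.CompositionSpec(library_size=5_000, n_samples=1, seed=3)
        reads_by_dataset, truth = simulate.generate_reads(spec, syn_ref)
        calls, _ = classify_reads(reads_by_dataset["ds1"], syn_ref)
        three_prime = calls["variant_class"].isin(["Trim3p", "Ext3p", "NTA"])
        assert calls.loc[three_prime, "seed_conserved"].all()
        five_prime = calls["variant_class"].isin(["Trim5p", "Ext5p"])
        assert not calls.loc[five_prime, "seed_conserved"].any()
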