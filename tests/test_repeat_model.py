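import pytest

from seedzip.errors import ContractViolation
from seedzip.repeat_model import (
    DictionaryEntry,
    EditOp,
    MismatchRecord,
    Occurrence,
    RepeatType,
    add_occurrence,
    apply_edits,
    dictionary_tsv,
    finalize_entry,
    materialize,
    variant_transform,
)


class TestMismatchRecord:
    def test_deletion_carries_no_base(self):
        with pytest.raises(ContractViolation):
            MismatchRecord(3, EditOp.DELETION, "A")

    def test_substitution_requires_base(self):
        with pytest.raises(ContractViolation):
            MismatchRecord(3, EditOp.SUBSTITUTION)


class TestDictionaryEntry:
    def test_worked_example_rows(self, table1_dictionary):
        e1, e2 = table1_dictionary.entries
        assert e1.extended_seed == "AATAACTTG"
        assert [
            (o.rtype, o.position, o.length) for o in e1.occurrences
        ] == [(RepeatType.APPROXIMATE, 5, 9), (RepeatType.REVERSE, 20, 9)]
        assert e2.occurrences[1].mismatches[0].op is EditOp.DELETION

    def test_mismatch_count_over_threshold_rejected(self):
        # floor(log2 9) = 3, so five edits cannot be recorded
        mms = tuple(
            MismatchRecord(p, EditOp.SUBSTITUTION, "A") for p in range(1, 6)
        )
        with pytest.raises(ContractViolation, match="threshold"):
            Occurrence(RepeatType.APPROXIMATE, 5, 9, mms)

    def test_mismatch_position_must_address_the_seed(self):
        entry = DictionaryEntry(extended_seed="ACGTACGTA", working_length=50)
        bad = Occurrence(
            RepeatType.APPROXIMATE, 5, 9,
            (MismatchRecord(11, EditOp.SUBSTITUTION, "A"),),
        )
        with pytest.raises(ContractViolation, match="outside"):
            add_occurrence(entry, bad)
        ins_at_end = Occurrence(
            RepeatType.APPROXIMATE, 5, 10,
            (MismatchRecord(10, EditOp.INSERTION, "A"),),
        )
        add_occurrence(entry, ins_at_end)  # l(i)+1 is legal for insertion

    def test_finalize_once(self):
        entry = DictionaryEntry(extended_seed="ACGTACGT", working_length=20)
        finalize_entry(entry, 17)
        assert entry.seed_position == 17
        with pytest.raises(ContractViolation):
            finalize_entry(entry, 3)
        with pytest.raises(ContractViolation):
            add_occurrence(entry, Occurrence(RepeatType.EXACT, 1, 8))


class TestVariantTransform:
    @pytest.mark.parametrize(
        "rtype,expected",
        [
            (RepeatType.EXACT, "ACGT"),
            (RepeatType.APPROXIMATE, "ACGT"),
            (RepeatType.TANDEM, "ACGT"),
            (RepeatType.REVERSE, "TGCA"),
            (RepeatType.COMPLEMENT, "TGCA"),
            (RepeatType.REVERSE_COMPLEMENT, "ACGT"),
        ],
    )
    def test_acgt_under_each_transform(self, rtype, expected):
        assert variant_transform("ACGT", rtype) == expected

    def test_transforms_are_involutions(self):
        for rtype in RepeatType:
            assert variant_transform(
                variant_transform("GATTACA", rtype), rtype
            ) == "GATTACA"


class TestApplyEdits:
    def test_substitution(self):
        e = (MismatchRecord(7, EditOp.SUBSTITUTION, "T"),)
        assert apply_edits("GCACTTACT", e) == "GCACTTTCT"

    def test_deletion(self):
        assert apply_edits("ACGT", (MismatchRecord(2, EditOp.DELETION),)) == "AGT"

    def test_insertion_before_and_append(self):
        assert apply_edits("ACGT", (MismatchRecord(1, EditOp.INSERTION, "T"),)) == "TACGT"
        assert apply_edits("ACGT", (MismatchRecord(5, EditOp.INSERTION, "G"),)) == "ACGTG"

    def test_insertion_then_substitution_at_same_position(self):
        e = (
            MismatchRecord(2, EditOp.INSERTION, "G"),
            MismatchRecord(2, EditOp.SUBSTITUTION, "T"),
        )
        assert apply_edits("ACGT", e) == "AGTGT"

    def test_materialize_reverse_with_edit(self):
        occ = Occurrence(
            RepeatType.REVERSE, 1, 4,
            (MismatchRecord(1, EditOp.SUBSTITUTION, "T"),),
        )
        # edited seed TCGT, reversed -> TGCT
        assert materialize("ACGT", occ) == "TGCT"

    def test_materialize_reverse_complement(self):
        occ = Occurrence(RepeatType.REVERSE_COMPLEMENT, 1, 5)
        assert materialize("AACGT", occ) == "ACGTT"


def test_dictionary_tsv_layout(table1_dictionary):
    text = dictionary_tsv(table1_dictionary)
    lines = text.strip().split("\n")
    assert lines[0].startswith("Extended seed\tType of repeat")
    assert lines[1].split("\t")[:4] == ["AATAACTTG", "Approx", "5", "9"]
    assert "(1 10 01, 8 10 00)" in lines[2]
    assert "(4 01)" in text  # deletion shown without a base field
    # one row per occurrence plus a seed row per entry
    assert len(lines) == 1 + 2 + 1 + 2 + 1
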