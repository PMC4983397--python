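import random

import pytest

from seedzip.container import (
    MAGIC,
    ParsedContainer,
    parse,
    serialize,
    serialize_with_audit,
)
from seedzip.errors import (
    ContractViolation,
    MalformedContainerError,
    NotAContainerError,
    UnsupportedVersionError,
)
from seedzip.fixtures import gen_random, repeat_family_fixture
from seedzip.match_engine import ExtendParams
from seedzip.pipeline import compress_to_parts
from seedzip.repeat_model import DictionaryEntry, OfflineDictionary
from seedzip.sequence_io import SanitizePolicy


def _entries_equal(a: DictionaryEntry, b: DictionaryEntry) -> bool:
    return (
        a.extended_seed == b.extended_seed
        and a.seed_position == b.seed_position
        and a.working_length == b.working_length
        and list(a.occurrences) == list(b.occurrences)
    )


class TestRoundTrip:
    def test_degenerate_container(self):
        data = serialize(OfflineDictionary(), "ACGT", ExtendParams())
        pc = parse(data)
        assert pc.parsed == "ACGT"
        assert len(pc.dictionary) == 0
        assert pc.params == ExtendParams()

    def test_worked_example_dictionary_field_for_field(self, table1_dictionary):
        data = serialize(
            table1_dictionary,
            "ACGTACGTAA",
            ExtendParams(k=8, lookahead=3),
            policy=SanitizePolicy.STRIP_RECORD,
            sidecar=((3, "N"), (7, "R")),
            original_length=112,
            name="tab1",
        )
        pc = parse(data)
        assert len(pc.dictionary) == 2
        for got, want in zip(pc.dictionary, table1_dictionary):
            assert _entries_equal(got, want)
        assert pc.parsed == "ACGTACGTAA"
        assert pc.sidecar == ((3, "N"), (7, "R"))
        assert pc.policy is SanitizePolicy.STRIP_RECORD
        assert pc.original_length == 112
        assert pc.name == "tab1"

    def test_synthetic_compress_runs_round_trip(self):
        rng = random.Random(31)
        for trial in range(25):
            if trial % 3 == 0:
                seq, _ = repeat_family_fixture(
                    length=rng.choice([600, 1200]),
                    density=rng.choice([0.3, 0.5]),
                    rng_seed=trial,
                    copy_length=60,
                    copies_per_family=4,
                )
            else:
                seq = gen_random(rng.randrange(0, 800), trial)
            params = ExtendParams(k=rng.choice([5, 8]))
            dictionary, parsed, _ = compress_to_parts(seq, params)
            data = serialize(
                dictionary, parsed, params, original_length=len(seq), name=seq.name
            )
            pc = parse(data)
            assert pc.parsed == parsed
            assert pc.params == params
            assert len(pc.dictionary) == len(dictionary)
            for got, want in zip(pc.dictionary, dictionary):
                assert _entries_equal(got, want)


class TestErrors:
    def test_random_bytes_are_not_a_container(self):
        with pytest.raises(NotAContainerError):
            parse(b"\x12\x34\x56\x78" * 8)

    def test_empty_input(self):
        with pytest.raises(NotAContainerError):
            parse(b"")

    def test_version_mismatch(self):
        data = bytearray(serialize(OfflineDictionary(), "ACGT", ExtendParams()))
        data[len(MAGIC)] = 99
        with pytest.raises(UnsupportedVersionError):
            parse(bytes(data))

    def test_truncation_is_malformed(self, table1_dictionary):
        data = serialize(table1_dictionary, "ACGTACGTAA", ExtendParams())
        with pytest.raises(MalformedContainerError):
            parse(data[: len(data) // 2])

    def test_unfinalized_entry_rejected(self):
        d = OfflineDictionary(
            entries=[DictionaryEntry(extended_seed="ACGTACGT", working_length=20)]
        )
        with pytest.raises(ContractViolation):
            serialize(d, "", ExtendParams())


class TestAudit:
    def test_categories_sum_to_file_bits(self, table1_dictionary):
        for dictionary, parsed in [
            (table1_dictionary, "ACGTACGTAA"),
            (OfflineDictionary(), "ACGT" * 100),
            (OfflineDictionary(), ""),
        ]:
            data, audit = serialize_with_audit(dictionary, parsed, ExtendParams())
            assert sum(audit.values()) == 8 * len(data)
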