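import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "seedzip",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("seedzip")


def planted_base_coverage(seq, truth, params=None):
    """Fraction of planted-repeat bases excised into the dictionary.

    Replays the compression trace forward over a list of original
    coordinates, so every excision can be mapped back to input positions.
    """
    from seedzip.match_engine import ExtendParams
    from seedzip.pipeline import compress_to_parts

    _, _, trace = compress_to_parts(seq, params or ExtendParams())
    orig = list(range(1, len(seq) + 1))
    covered = set()
    for ev in trace.events:
        covered.update(orig[ev.position - 1 : ev.position - 1 + ev.length])
        del orig[ev.position - 1 : ev.position - 1 + ev.length]
    planted = set()
    for t in truth:
        planted.update(range(t.start, t.end + 1))
    if not planted:
        return 1.0
    return len(planted & covered) / len(planted)


@pytest.fixture
def table1_dictionary():
    """The two-entry dictionary printed as the method's worked example.

    Entry 1: seed AATAACTTG with an approximate occurrence (c=5, n0=9) and
    a reverse occurrence (c=20, n0=9) carrying substitutions (1,C) and
    (8,A).  Entry 2: seed AACTTG with a reverse occurrence (c=36, n0=6)
    and an approximate occurrence (c=73, n0=7) carrying one deletion at 4.
    Seed positions d and working lengths are chosen here; the published
    table does not fix them.
    """
    from seedzip.repeat_model import (
        DictionaryEntry,
        EditOp,
        MismatchRecord,
        Occurrence,
        OfflineDictionary,
        RepeatType,
        add_occurrence,
        finalize_entry,
    )

    e1 = DictionaryEntry(extended_seed="AATAACTTG", working_length=100)
    add_occurrence(e1, Occurrence(RepeatType.APPROXIMATE, 5, 9))
    add_occurrence(
        e1,
        Occurrence(
            RepeatType.REVERSE,
            20,
            9,
            (
                MismatchRecord(1, EditOp.SUBSTITUTION, "C"),
                MismatchRecord(8, EditOp.SUBSTITUTION, "A"),
            ),
        ),
    )
    finalize_entry(e1, 17)
    e2 = DictionaryEntry(extended_seed="AACTTG", working_length=82)
    add_occurrence(e2, Occurrence(RepeatType.REVERSE, 36, 6))
    add_occurrence(
        e2,
        Occurrence(
            RepeatType.APPROXIMATE,
            73,
            7,
            (MismatchRecord(4, EditOp.DELETION),),
        ),
    )
    finalize_entry(e2, 42)
    return OfflineDictionary(entries=[e1, e2])
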