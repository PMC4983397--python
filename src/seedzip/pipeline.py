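"""Compression and decompression orchestration.

Compression repeatedly (1) scans the working sequence for the next seed
with a match under any orientation transform, (2) extends seed and match
to the maximal extended seed/repeat pair, (3) sweeps the working sequence
for every further full occurrence of the extended seed, (4) excises the
qualifying occurrences left to right (recording each position against the
sequence as it stands at that excision) and finally excises the extended
seed itself, recording its position ``d`` last.  The loop restarts on the
shortened sequence until no seed commits an entry; the residue is the
final parsed sequence, and dictionary plus arithmetic-coded residue form
the compressed container.

An entry is committed only when it pays for itself: the idealized
dictionary cost of the entry (vocabulary, positions, lengths, types,
mismatch triples, plus the seed-position term) must be strictly below the
two bits per base the excised symbols would otherwise cost in the parsed
sequence, and only occurrences with positive individual gain are kept.
Chance k-mer matches of a patternless sequence fail this test, so its
dictionary stays empty and the output stays at the entropy-coding
baseline.

Decompression replays the record in reverse: entries in reverse creation
order, reinserting the seed at ``d`` first, then each occurrence in
reverse excision order, materialized by applying its mismatch edits to
the seed and the orientation transform of its repeat type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from . import container as container_mod
from .errors import ContractViolation, IntegrityError
from .match_engine import (
    AnchoredOccurrence,
    ExtendParams,
    build_kmer_index,
    extend,
    find_next_match,
    find_seed_occurrences,
)
from .metrics import ceil_log2, occurrence_gain
from .repeat_model import (
    DictionaryEntry,
    Occurrence,
    OfflineDictionary,
    add_occurrence,
    finalize_entry,
    materialize,
)
from .sequence_io import DnaSequence, SanitizePolicy, reinsert_sidecar


@dataclass(frozen=True)
class TraceEvent:
    """One excision: an occurrence (kind='occurrence') or a seed (kind='seed')."""

    kind: str
    pass_no: int
    entry_index: int
    position: int
    length: int


@dataclass
class CompressionTrace:
    """Ordered excision log; replaying it backwards rebuilds the input."""

    events: List[TraceEvent] = field(default_factory=list)

    def replay_backwards(self, parsed: str, dictionary: OfflineDictionary) -> str:
        """Reconstruct the input from the parsed residue using the trace."""
        seq = parsed
        for ev in reversed(self.events):
            entry = dictionary.entries[ev.entry_index]
            if ev.kind == "seed":
                frag = entry.extended_seed
            else:
                occ = next(
                    o
                    for o in entry.occurrences
                    if o.position == ev.position and o.length == ev.length
                )
                frag = materialize(entry.extended_seed, occ)
            if ev.position > len(seq) + 1 or len(frag) != ev.length:
                raise IntegrityError("trace does not fit the parsed sequence")
            seq = seq[: ev.position - 1] + frag + seq[ev.position - 1 :]
        return seq


def _entry_commit(
    seed_span: Tuple[int, int],
    candidates: List[AnchoredOccurrence],
) -> Tuple[bool, List[AnchoredOccurrence], int]:
    """Decide whether excising ``candidates`` against this seed pays off.

    Returns (commit?, kept occurrences, the seed's post-excision position).
    Gains are idealized Eq-style bit counts; the vocabulary cost of the
    seed cancels against the two bits per base its own excision saves, so
    the entry-level overhead left is the seed-position term.
    """
    d, q = seed_span
    seed_len = q - d + 1
    kept = []
    total = 0
    for cand in candidates:
        occ = Occurrence(
            rtype=cand.rtype,
            position=cand.repeat_span[0],
            length=cand.n0,
            mismatches=cand.mismatches,
        )
        gain = occurrence_gain(occ, seed_len)
        if gain > 0:
            kept.append(cand)
            total += gain
    if not kept:
        return False, [], d
    shift = sum(c.n0 for c in kept if c.repeat_span[1] < d)
    d_final = d - shift
    return total > ceil_log2(d_final), kept, d_final


def compress_to_parts(
    seq: DnaSequence,
    params: ExtendParams = ExtendParams(),
    max_passes: Optional[int] = None,
) -> Tuple[OfflineDictionary, str, CompressionTrace]:
    """Run the search loop; return (dictionary, parsed residue, trace)."""
    working = seq.symbols
    k = params.k
    dictionary = OfflineDictionary()
    trace = CompressionTrace()
    pass_no = 0
    while len(working) >= 2 * k:
        if max_passes is not None and pass_no >= max_passes:
            break
        pass_no += 1
        index = build_kmer_index(working, k)
        seed_start = 1
        committed = False
        while not committed:
            found = find_next_match(working, k, seed_start, index=index)
            if found is None:
                break
            seed, match_start, transform = found
            ext = extend(working, seed, match_start, transform, params)
            d, q = ext.seed_span
            primary = AnchoredOccurrence(
                repeat_span=ext.repeat_span,
                n0=ext.n0,
                mismatches=ext.mismatches,
                rtype=ext.rtype,
            )
            others = find_seed_occurrences(
                working,
                (d, q),
                core_offset=seed.a - d,
                k=k,
                params=params,
                exclude=[ext.repeat_span],
                index=index,
            )
            candidates = sorted(
                [primary, *others], key=lambda o: o.repeat_span[0]
            )
            commit, kept, _ = _entry_commit((d, q), candidates)
            if not commit:
                seed_start = seed.a + 1
                continue
            working = _excise_entry(
                working, (d, q), kept, dictionary, trace, pass_no
            )
            committed = True
        if not committed:
            break
    return dictionary, working, trace


def _excise_entry(
    working: str,
    seed_span: Tuple[int, int],
    kept: List[AnchoredOccurrence],
    dictionary: OfflineDictionary,
    trace: CompressionTrace,
    pass_no: int,
) -> str:
    """Excise occurrences left to right, then the seed; record the entry."""
    d, q = seed_span
    seed_str = working[d - 1 : q]
    entry = DictionaryEntry(
        extended_seed=seed_str, working_length=len(working)
    )
    entry_index = len(dictionary.entries)
    removed = 0
    seed_shift = 0
    for cand in kept:  # already sorted left to right, spans disjoint
        c0, p0 = cand.repeat_span
        c, p = c0 - removed, p0 - removed
        occ = Occurrence(
            rtype=cand.rtype,
            position=c,
            length=cand.n0,
            mismatches=cand.mismatches,
        )
        if materialize(seed_str, occ) != working[c - 1 : p]:
            raise ContractViolation(
                "dictionary record does not reproduce the excised repeat"
            )
        add_occurrence(entry, occ)
        working = working[: c - 1] + working[p:]
        trace.events.append(
            TraceEvent("occurrence", pass_no, entry_index, c, cand.n0)
        )
        removed += cand.n0
        if p0 < d:
            seed_shift += cand.n0
    d_final = d - seed_shift
    if working[d_final - 1 : d_final - 1 + len(seed_str)] != seed_str:
        raise ContractViolation("seed drifted during occurrence excision")
    finalize_entry(entry, d_final)
    working = working[: d_final - 1] + working[d_final - 1 + len(seed_str) :]
    trace.events.append(
        TraceEvent("seed", pass_no, entry_index, d_final, len(seed_str))
    )
    dictionary.entries.append(entry)
    return working


def compress(
    seq: DnaSequence,
    params: ExtendParams = ExtendParams(),
    max_passes: Optional[int] = None,
) -> bytes:
    """Compress a sanitized sequence to container bytes (deterministic)."""
    dictionary, parsed, _ = compress_to_parts(seq, params, max_passes)
    policy = (
        SanitizePolicy.STRIP_RECORD if seq.sidecar else SanitizePolicy.REJECT
    )
    return container_mod.serialize(
        dictionary,
        parsed,
        params,
        policy=policy,
        sidecar=seq.sidecar,
        original_length=len(seq) + len(seq.sidecar),
        name=seq.name,
    )


def decompress_parts(parsed_container: container_mod.ParsedContainer) -> str:
    """Reverse-replay a parsed container back to the sanitized sequence."""
    seq = parsed_container.parsed
    for entry in reversed(parsed_container.dictionary.entries):
        d = entry.seed_position
        if d is None or d > len(seq) + 1:
            raise IntegrityError(
                "seed position outside the sequence during replay"
            )
        seq = seq[: d - 1] + entry.extended_seed + seq[d - 1 :]
        for occ in reversed(entry.occurrences):
            frag = materialize(entry.extended_seed, occ)
            if len(frag) != occ.length:
                raise IntegrityError(
                    "materialized repeat length disagrees with the record"
                )
            if occ.position > len(seq) + 1:
                raise IntegrityError(
                    "occurrence position outside the sequence during replay"
                )
            seq = seq[: occ.position - 1] + frag + seq[occ.position - 1 :]
    return seq


def decompress(data: bytes) -> DnaSequence:
    """Restore the original sequence from container bytes.

    The returned sequence carries the sanitize sidecar, so
    :func:`~seedzip.sequence_io.reinsert_sidecar` (or :func:`restore_raw`)
    yields the raw record including any stripped non-ACGT symbols.  The
    restored length is verified against the header.
    """
    pc = container_mod.parse(data)
    seq = decompress_parts(pc)
    raw = reinsert_sidecar(seq, pc.sidecar)
    if len(raw) != pc.original_length:
        raise IntegrityError(
            f"restored length {len(raw)} != recorded {pc.original_length}"
        )
    return DnaSequence(symbols=seq, name=pc.name, sidecar=pc.sidecar)


def restore_raw(seq: DnaSequence) -> str:
    """The raw record: sanitized symbols with sidecar symbols reinserted."""
    return reinsert_sidecar(seq.symbols, seq.sidecar)
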