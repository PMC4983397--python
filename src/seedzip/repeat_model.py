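"""Domain model for seeds, repeat occurrences, mismatches and the dictionary.

The offline dictionary is a table with one entry per *extended seed*: the
seed string itself, every occurrence excised against it (repeat type,
position at excision time, length, mismatch triples), and finally the
seed's own excision position ``d``.  Entry order is the excision order;
decompression replays it in reverse.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .errors import ContractViolation

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class RepeatType(enum.Enum):
    """The six repeat classes, with their fixed 3-bit container codes."""

    EXACT = 0b000
    APPROXIMATE = 0b001
    REVERSE = 0b010
    COMPLEMENT = 0b011
    REVERSE_COMPLEMENT = 0b100
    TANDEM = 0b101

    @property
    def is_reversed(self) -> bool:
        """True when seed and repeat run in opposite directions."""
        return self in (RepeatType.REVERSE, RepeatType.REVERSE_COMPLEMENT)

    @property
    def is_complemented(self) -> bool:
        """True when paired bases are complements rather than equal."""
        return self in (RepeatType.COMPLEMENT, RepeatType.REVERSE_COMPLEMENT)


class EditOp(enum.Enum):
    """Edit operations with their fixed 2-bit codes (11 is unassigned)."""

    INSERTION = 0b00
    DELETION = 0b01
    SUBSTITUTION = 0b10


#: Fixed 2-bit base codes: A=00, C=01, G=10, T=11.
BASE_CODES = {"A": 0b00, "C": 0b01, "G": 0b10, "T": 0b11}
BASE_FROM_CODE = {v: k for k, v in BASE_CODES.items()}


def mismatch_limit(n0: int) -> int:
    """floor(log2(n0)): the dynamic cap on edits in a repeat of length n0."""
    if n0 < 1:
        raise ContractViolation(f"repeat length must be >= 1, got {n0}")
    return n0.bit_length() - 1


@dataclass(frozen=True)
class MismatchRecord:
    """One edit as a (P, E, S) triple.

    ``position`` (P) is 1-based within the extended seed; for an insertion
    it names the seed position the new symbol goes *before* and may be
    ``seed length + 1`` (append).  ``base`` (S) is the inserted or
    substituted symbol in seed orientation and must be absent exactly when
    the operation is a deletion.
    """

    position: int
    op: EditOp
    base: Optional[str] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ContractViolation(f"mismatch position must be >= 1, got {self.position}")
        if self.op is EditOp.DELETION:
            if self.base is not None:
                raise ContractViolation("deletion records carry no base symbol")
        else:
            if self.base not in BASE_CODES:
                raise ContractViolation(
                    f"{self.op.name.lower()} requires a base in ACGT, got {self.base!r}"
                )


@dataclass(frozen=True)
class Occurrence:
    """One excised repeat: type, position at excision time, length, edits."""

    rtype: RepeatType
    position: int  # c: 1-based start in the working sequence when excised
    length: int  # n0: number of symbols excised
    mismatches: Tuple[MismatchRecord, ...] = ()

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ContractViolation(f"occurrence position must be >= 1, got {self.position}")
        if self.length < 1:
            raise ContractViolation(f"occurrence length must be >= 1, got {self.length}")
        if len(self.mismatches) > mismatch_limit(self.length):
            raise ContractViolation(
                f"{len(self.mismatches)} mismatches exceed the floor(log2({self.length}))"
                f"={mismatch_limit(self.length)} threshold"
            )


@dataclass
class DictionaryEntry:
    """An extended seed, its occurrences, and (once finalized) its position d.

    ``working_length`` is the length of the working sequence at the moment
    the entry was created; the container sizes this entry's position and
    length fields against it.
    """

    extended_seed: str
    occurrences: List[Occurrence] = field(default_factory=list)
    seed_position: Optional[int] = None  # d, set exactly once by finalize
    working_length: int = 0

    @property
    def finalized(self) -> bool:
        return self.seed_position is not None


def add_occurrence(entry: DictionaryEntry, occ: Occurrence) -> DictionaryEntry:
    """Append one occurrence, checking it against the entry's seed."""
    if entry.finalized:
        raise ContractViolation("cannot add occurrences to a finalized entry")
    seed_len = len(entry.extended_seed)
    for m in occ.mismatches:
        limit = seed_len + 1 if m.op is EditOp.INSERTION else seed_len
        if m.position > limit:
            raise ContractViolation(
                f"mismatch position {m.position} outside the {seed_len}-symbol seed"
            )
    entry.occurrences.append(occ)
    return entry


def finalize_entry(entry: DictionaryEntry, d: int) -> DictionaryEntry:
    """Record the seed's own excision position; the entry is immutable after."""
    if entry.finalized:
        raise ContractViolation("entry already finalized")
    if d < 1:
        raise ContractViolation(f"seed position must be >= 1, got {d}")
    entry.seed_position = d
    return entry


@dataclass
class OfflineDictionary:
    """Ordered list of entries; order is the excision (creation) order."""

    entries: List[DictionaryEntry] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# Materialization: turning (seed, occurrence) back into the excised string.
# ---------------------------------------------------------------------------

def variant_transform(fragment: str, rtype: RepeatType) -> str:
    """Apply a repeat type's transform to a fragment.

    Forward classes (exact/approximate/tandem) return the fragment
    unchanged; reverse reverses, complement maps A<->T and C<->G in place,
    reverse_complement does both.
    """
    out = fragment
    if rtype.is_complemented:
        out = out.translate(_COMPLEMENT)
    if rtype.is_reversed:
        out = out[::-1]
    return out


def apply_edits(seed: str, edits: Sequence[MismatchRecord]) -> str:
    """Apply (P, E, S) edits to a seed, in list order, positions ascending.

    At each seed position insertions recorded *before* that position are
    emitted first (in list order), then the position's own symbol is
    copied, substituted or dropped.  Insertions at ``len(seed) + 1``
    append at the right end.
    """
    out: List[str] = []
    idx = 0
    n = len(seed)
    for p in range(1, n + 2):
        while (
            idx < len(edits)
            and edits[idx].position == p
            and edits[idx].op is EditOp.INSERTION
        ):
            out.append(edits[idx].base)  # type: ignore[arg-type]
            idx += 1
        if p > n:
            break
        if idx < len(edits) and edits[idx].position == p:
            e = edits[idx]
            idx += 1
            if e.op is EditOp.SUBSTITUTION:
                out.append(e.base)  # type: ignore[arg-type]
            elif e.op is EditOp.DELETION:
                pass
            else:  # pragma: no cover - insertions consumed above
                raise ContractViolation("unordered edit list")
        else:
            out.append(seed[p - 1])
    if idx != len(edits):
        raise ContractViolation("edit positions exceed the seed length")
    return "".join(out)


def materialize(seed: str, occ: Occurrence) -> str:
    """Reconstruct the excised repeat string from its dictionary record."""
    return variant_transform(apply_edits(seed, occ.mismatches), occ.rtype)


# ---------------------------------------------------------------------------
# Human-readable dump mirroring the dictionary's tabular layout.
# ---------------------------------------------------------------------------

_TSV_HEADER = "Extended seed\tType of repeat\tPosition of repeat\tLength\tMismatch details"


def _format_mismatches(mismatches: Sequence[MismatchRecord]) -> str:
    from .mismatch_codec import format_triple  # local import: avoid cycle

    if not mismatches:
        return ""
    return "(" + ", ".join(format_triple(m) for m in mismatches) + ")"


def dictionary_tsv(dictionary: OfflineDictionary) -> str:
    """Dump the dictionary as TSV: seed / type / position / length / mismatches.

    Each entry's occurrences appear on consecutive rows (the seed shown on
    the first), followed by a row recording the seed's own position d.
    """
    lines = [_TSV_HEADER]
    for entry in dictionary:
        first = True
        for occ in entry.occurrences:
            seed_cell = entry.extended_seed if first else ""
            first = False
            tname = "Approx" if occ.rtype in (RepeatType.EXACT, RepeatType.APPROXIMATE) else occ.rtype.name.replace("_", " ").title()
            lines.append(
                f"{seed_cell}\t{tname}\t{occ.position}\t{occ.length}\t"
                f"{_format_mismatches(occ.mismatches)}"
            )
        seed_cell = entry.extended_seed if first else ""
        lines.append(f"{seed_cell}\tSeed\t{entry.seed_position}\t{len(entry.extended_seed)}\t")
    return "\n".join(lines) + "\n"
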