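"""Bit-level encoding of mismatch triples (P, E, S).

Field codes are fixed constants: edit operations are 00 insertion,
01 deletion, 10 substitution (11 is unassigned), and bases are A=00,
C=01, G=10, T=11.  The base field is omitted for deletions.

Two position encodings exist:

* ``canonical`` — P written in a fixed ``width_P`` bits so the stream is
  self-delimiting; this is what the container stores.  Per dictionary
  entry the width is ``ceil(log2(l(i) + 2))`` bits, which admits an
  insertion at position ``l(i) + 1``.
* ``minimal`` — P written in exactly ``ceil(log2(P + 1))`` bits (its
  minimal binary form).  Not self-delimiting; it exists for display and
  verification of worked examples, never in the container.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

from .errors import ContractViolation, MalformedContainerError
from .repeat_model import BASE_CODES, BASE_FROM_CODE, EditOp, MismatchRecord

_OP_FROM_CODE = {op.value: op for op in EditOp}


def width_for_seed(seed_length: int) -> int:
    """Canonical position width for an entry: ceil(log2(l(i) + 2)) bits."""
    if seed_length < 1:
        raise ContractViolation("seed length must be >= 1")
    return (seed_length + 1).bit_length()


def triple_bit_cost(m: MismatchRecord, width_P: int) -> int:
    """Canonical bit cost: width_P + 2, plus 2 more unless E is a deletion."""
    return width_P + 2 + (0 if m.op is EditOp.DELETION else 2)


@dataclass(frozen=True)
class TripleBits:
    """An encoded triple: the bit string and the position width used."""

    bits: str
    width_P: int

    def __post_init__(self) -> None:
        if set(self.bits) - {"0", "1"}:
            raise ContractViolation("bits must be a 0/1 string")


def encode_triple(
    m: MismatchRecord, width_P: int = 0, mode: str = "canonical"
) -> TripleBits:
    """Encode one (P, E, S) triple as position bits ‖ op bits ‖ base bits.

    In canonical mode ``width_P`` must be given and P must fit in it; in
    minimal mode the position takes exactly its minimal binary width and
    ``width_P`` is ignored.
    """
    if mode == "minimal":
        width = m.position.bit_length()
        pos_bits = format(m.position, "b")
    elif mode == "canonical":
        if width_P < 1:
            raise ContractViolation("canonical mode requires width_P >= 1")
        if m.position >= (1 << width_P):
            raise ContractViolation(
                f"position {m.position} does not fit in {width_P} bits"
            )
        width = width_P
        pos_bits = format(m.position, f"0{width_P}b")
    else:
        raise ContractViolation(f"unknown triple mode {mode!r}")
    bits = pos_bits + format(m.op.value, "02b")
    if m.op is not EditOp.DELETION:
        bits += format(BASE_CODES[m.base], "02b")
    return TripleBits(bits=bits, width_P=width)


def decode_triple(
    bits: str,
    width_P: int,
    offset: int = 0,
    deletion_base_dialect: bool = False,
) -> Tuple[MismatchRecord, int]:
    """Decode one canonical triple from ``bits`` starting at ``offset``.

    Returns the record and the number of bits consumed.  With
    ``deletion_base_dialect`` a base field following a deletion is read
    and discarded, accepting the redundant written form of the triple.
    """
    need = width_P + 2
    if len(bits) - offset < need:
        raise MalformedContainerError("triple truncated before the op field")
    pos = int(bits[offset : offset + width_P], 2)
    op_code = int(bits[offset + width_P : offset + need], 2)
    if op_code not in _OP_FROM_CODE:
        raise MalformedContainerError("edit-op code 11 is unassigned")
    op = _OP_FROM_CODE[op_code]
    consumed = need
    base = None
    if op is not EditOp.DELETION or deletion_base_dialect:
        if len(bits) - offset < consumed + 2:
            raise MalformedContainerError("triple truncated in the base field")
        code = int(bits[offset + consumed : offset + consumed + 2], 2)
        consumed += 2
        if op is not EditOp.DELETION:
            base = BASE_FROM_CODE[code]
    return MismatchRecord(position=pos, op=op, base=base), consumed


def mismatches_between(seed: str, repeat: str) -> Tuple[MismatchRecord, ...]:
    """Substitution triples for two equal-length fragments, left to right."""
    if len(seed) != len(repeat):
        raise ContractViolation(
            "position-wise comparison requires equal-length fragments"
        )
    return tuple(
        MismatchRecord(position=i + 1, op=EditOp.SUBSTITUTION, base=y)
        for i, (x, y) in enumerate(zip(seed, repeat))
        if x != y
    )


def format_triple(m: MismatchRecord) -> str:
    """Display form '<P> <op bits> <base bits>' (base omitted for deletion)."""
    parts = [str(m.position), format(m.op.value, "02b")]
    if m.op is not EditOp.DELETION:
        parts.append(format(BASE_CODES[m.base], "02b"))
    return " ".join(parts)
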