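"""The ``.szp`` compressed container: bit-exact serialization and parsing.

Layout (all multi-bit integers big-endian; one bit stream, padded with
zeros to a byte boundary only at the end of the file):

====================  ======  ====================================================
field                 bits    meaning
====================  ======  ====================================================
magic                 32      ASCII ``SZPC``
version               8       format version (currently 1)
k                     8       seed length used by the compressor
lookahead             8       gain-rule look-ahead
threshold mode        8       0 = log2_n0, 1 = log2_log2_n0
sanitize policy       8       0 = reject, 1 = strip-record
name length           16      record identifier byte count
name                  8/byte  UTF-8 record identifier
sidecar count         32      number of stripped non-ACGT symbols
per sidecar item      32+8    1-based original position, ASCII symbol
original length       32      restored sequence length (verified on decompress)
entry count n         32      dictionary size
--- per entry ---
L_w                   32      working-sequence length at entry creation;
                              W = ceil(log2(L_w + 1)) sizes this entry's
                              position and length fields
l(i)                  W       extended-seed length
seed stream           var     arithmetic-coded seed (self-delimiting)
k(i)                  W       occurrence count
--- per occurrence ---
repeat type           3       :class:`~seedzip.repeat_model.RepeatType` code
position c            W       start at excision time
length n0             W       symbols excised
mismatch count        6       number of (P,E,S) triples
triples               var     canonical triples, width_P = ceil(log2(l(i)+2))
--- end occurrences ---
seed position d       W       the entry's final excision position
--- end entries ---
parsed stream         var     arithmetic-coded final parsed sequence
padding               0..7    zeros to the byte boundary
====================  ======  ====================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .entropy_codec import ac_decode, ac_encode
from .errors import (
    ContractViolation,
    MalformedContainerError,
    NotAContainerError,
    UnsupportedVersionError,
)
from .match_engine import ExtendParams
from .mismatch_codec import decode_triple, encode_triple, width_for_seed
from .repeat_model import (
    DictionaryEntry,
    Occurrence,
    OfflineDictionary,
    RepeatType,
)
from .sequence_io import SanitizePolicy, SidecarItem

MAGIC = b"SZPC"
VERSION = 1
FILE_EXTENSION = ".szp"

_THRESHOLD_CODES = {"log2_n0": 0, "log2_log2_n0": 1}
_THRESHOLD_FROM_CODE = {v: k for k, v in _THRESHOLD_CODES.items()}
_POLICY_CODES = {SanitizePolicy.REJECT: 0, SanitizePolicy.STRIP_RECORD: 1}
_POLICY_FROM_CODE = {v: k for k, v in _POLICY_CODES.items()}
_RTYPE_FROM_CODE = {t.value: t for t in RepeatType}

#: Audit categories; their bit counts always sum to the file bit-length.
AUDIT_KEYS = (
    "vocabulary", "positions", "lengths", "type", "mismatch", "parsed", "overhead",
)


class _BitWriter:
    __slots__ = ("parts", "nbits")

    def __init__(self) -> None:
        self.parts: List[str] = []
        self.nbits = 0

    def write_uint(self, value: int, width: int) -> None:
        if value < 0 or value >= (1 << width):
            raise ContractViolation(f"{value} does not fit in {width} bits")
        self.parts.append(format(value, f"0{width}b"))
        self.nbits += width

    def write_bits(self, bits: str) -> None:
        self.parts.append(bits)
        self.nbits += len(bits)

    def to_bytes(self) -> Tuple[bytes, int]:
        """Pack to bytes, returning (bytes, padding bits appended)."""
        pad = (-self.nbits) % 8
        bits = "".join(self.parts) + "0" * pad
        return (
            int(bits, 2).to_bytes(len(bits) // 8, "big") if bits else b"",
            pad,
        )


class _BitReader:
    __slots__ = ("bits", "pos")

    def __init__(self, data: bytes) -> None:
        self.bits = "".join(format(b, "08b") for b in data)
        self.pos = 0

    def read_uint(self, width: int) -> int:
        if self.pos + width > len(self.bits):
            raise MalformedContainerError("container truncated")
        value = int(self.bits[self.pos : self.pos + width], 2) if width else 0
        self.pos += width
        return value

    @property
    def remaining(self) -> int:
        return len(self.bits) - self.pos


@dataclass(frozen=True)
class ParsedContainer:
    """Everything :func:`parse` recovers from a container."""

    dictionary: OfflineDictionary
    parsed: str
    params: ExtendParams
    policy: SanitizePolicy
    sidecar: Tuple[SidecarItem, ...]
    original_length: int
    name: str = ""


def _field_width(working_length: int) -> int:
    """Fixed width for positions/lengths: ceil(log2(L_w + 1)) bits."""
    if working_length < 1:
        raise ContractViolation("working length must be >= 1")
    return working_length.bit_length()


def serialize(
    dictionary: OfflineDictionary,
    parsed: str,
    params: ExtendParams,
    *,
    policy: SanitizePolicy = SanitizePolicy.REJECT,
    sidecar: Tuple[SidecarItem, ...] = (),
    original_length: Optional[int] = None,
    name: str = "",
) -> bytes:
    return serialize_with_audit(
        dictionary,
        parsed,
        params,
        policy=policy,
        sidecar=sidecar,
        original_length=original_length,
        name=name,
    )[0]


def serialize_with_audit(
    dictionary: OfflineDictionary,
    parsed: str,
    params: ExtendParams,
    *,
    policy: SanitizePolicy = SanitizePolicy.REJECT,
    sidecar: Tuple[SidecarItem, ...] = (),
    original_length: Optional[int] = None,
    name: str = "",
) -> Tuple[bytes, Dict[str, int]]:
    """Serialize, returning the bytes and an itemized bit-count audit.

    The audit maps each :data:`AUDIT_KEYS` category to its exact bit count;
    the categories sum to ``8 * len(bytes)``.
    """
    if original_length is None:
        original_length = (
            len(parsed)
            + sum(
                len(e.extended_seed) + sum(o.length for o in e.occurrences)
                for e in dictionary
            )
            + len(sidecar)
        )
    audit = {key: 0 for key in AUDIT_KEYS}
    w = _BitWriter()

    def tracked(category: str, fn, *args) -> None:
        before = w.nbits
        fn(*args)
        audit[category] += w.nbits - before

    name_bytes = name.encode("utf-8")
    if len(name_bytes) > 0xFFFF:
        raise ContractViolation("record name longer than 65535 bytes")

    def write_header() -> None:
        for byte in MAGIC:
            w.write_uint(byte, 8)
        w.write_uint(VERSION, 8)
        w.write_uint(params.k, 8)
        w.write_uint(params.lookahead, 8)
        w.write_uint(_THRESHOLD_CODES[params.threshold_mode], 8)
        w.write_uint(_POLICY_CODES[policy], 8)
        w.write_uint(len(name_bytes), 16)
        for byte in name_bytes:
            w.write_uint(byte, 8)
        w.write_uint(len(sidecar), 32)
        for pos, sym in sidecar:
            w.write_uint(pos, 32)
            w.write_uint(ord(sym), 8)
        w.write_uint(original_length, 32)
        w.write_uint(len(dictionary), 32)

    tracked("overhead", write_header)

    for entry in dictionary:
        if not entry.finalized:
            raise ContractViolation("cannot serialize an unfinalized entry")
        seed_len = len(entry.extended_seed)
        fw = _field_width(entry.working_length)
        width_p = width_for_seed(seed_len)
        tracked("overhead", w.write_uint, entry.working_length, 32)
        tracked("lengths", w.write_uint, seed_len, fw)
        tracked("vocabulary", w.write_bits, ac_encode(entry.extended_seed))
        tracked("overhead", w.write_uint, len(entry.occurrences), fw)
        for occ in entry.occurrences:
            tracked("type", w.write_uint, occ.rtype.value, 3)
            tracked("positions", w.write_uint, occ.position, fw)
            tracked("lengths", w.write_uint, occ.length, fw)
            tracked("overhead", w.write_uint, len(occ.mismatches), 6)
            for m in occ.mismatches:
                tracked("mismatch", w.write_bits, encode_triple(m, width_p).bits)
        tracked("positions", w.write_uint, entry.seed_position, fw)

    tracked("parsed", w.write_bits, ac_encode(parsed))
    data, pad = w.to_bytes()
    audit["overhead"] += pad
    assert sum(audit.values()) == 8 * len(data)
    return data, audit


def parse(data: bytes) -> ParsedContainer:
    """Exact inverse of :func:`serialize`."""
    if len(data) < len(MAGIC) or data[: len(MAGIC)] != MAGIC:
        raise NotAContainerError("missing SZPC magic; not a seedzip container")
    reader = _BitReader(data)
    reader.pos = len(MAGIC) * 8
    version = reader.read_uint(8)
    if version != VERSION:
        raise UnsupportedVersionError(
            f"container version {version} is not supported (expected {VERSION})"
        )
    k = reader.read_uint(8)
    lookahead = reader.read_uint(8)
    threshold_code = reader.read_uint(8)
    if threshold_code not in _THRESHOLD_FROM_CODE:
        raise MalformedContainerError(f"unknown threshold mode code {threshold_code}")
    policy_code = reader.read_uint(8)
    if policy_code not in _POLICY_FROM_CODE:
        raise MalformedContainerError(f"unknown sanitize policy code {policy_code}")
    try:
        params = ExtendParams(
            k=k, lookahead=lookahead,
            threshold_mode=_THRESHOLD_FROM_CODE[threshold_code],
        )
    except ContractViolation as exc:
        raise MalformedContainerError(f"invalid parameters in header: {exc}") from exc
    name_len = reader.read_uint(16)
    name = bytes(reader.read_uint(8) for _ in range(name_len)).decode("utf-8")
    sidecar_count = reader.read_uint(32)
    sidecar = tuple(
        (reader.read_uint(32), chr(reader.read_uint(8)))
        for _ in range(sidecar_count)
    )
    original_length = reader.read_uint(32)
    n_entries = reader.read_uint(32)

    entries: List[DictionaryEntry] = []
    try:
        for _ in range(n_entries):
            working_length = reader.read_uint(32)
            fw = _field_width(working_length)
            seed_len = reader.read_uint(fw)
            seed, consumed = ac_decode(reader.bits, reader.pos)
            reader.pos += consumed
            if len(seed) != seed_len:
                raise MalformedContainerError(
                    f"decoded seed length {len(seed)} != recorded {seed_len}"
                )
            width_p = width_for_seed(seed_len)
            entry = DictionaryEntry(
                extended_seed=seed, working_length=working_length
            )
            occ_count = reader.read_uint(fw)
            for _ in range(occ_count):
                rtype_code = reader.read_uint(3)
                if rtype_code not in _RTYPE_FROM_CODE:
                    raise MalformedContainerError(
                        f"unknown repeat-type code {rtype_code}"
                    )
                position = reader.read_uint(fw)
                length = reader.read_uint(fw)
                mm_count = reader.read_uint(6)
                mismatches = []
                for _ in range(mm_count):
                    if reader.remaining < width_p + 2:
                        raise MalformedContainerError("container truncated")
                    record, consumed = decode_triple(
                        reader.bits, width_p, offset=reader.pos
                    )
                    reader.pos += consumed
                    mismatches.append(record)
                entry.occurrences.append(
                    Occurrence(
                        rtype=_RTYPE_FROM_CODE[rtype_code],
                        position=position,
                        length=length,
                        mismatches=tuple(mismatches),
                    )
                )
            entry.seed_position = reader.read_uint(fw)
            entries.append(entry)
        parsed, consumed = ac_decode(reader.bits, reader.pos)
        reader.pos += consumed
    except ContractViolation as exc:
        raise MalformedContainerError(f"inconsistent container fields: {exc}") from exc
    if reader.remaining >= 8 or any(
        b == "1" for b in reader.bits[reader.pos :]
    ):
        raise MalformedContainerError("trailing data after the parsed stream")
    return ParsedContainer(
        dictionary=OfflineDictionary(entries=entries),
        parsed=parsed,
        params=params,
        policy=_POLICY_FROM_CODE[policy_code],
        sidecar=sidecar,
        original_length=original_length,
        name=name,
    )
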