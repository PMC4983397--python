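"""FASTA input/output, sequence validation and the coordinate convention.

All positions handed to users or stored in dictionary entries are 1-based
and inclusive: ``S_i`` is the i-th symbol of a sequence ``S`` of length
``l`` with ``1 <= i <= l``.  Internal 0-based indexing is converted at the
module boundary.

Non-ACGT handling is controlled by a :class:`SanitizePolicy`.  Under
``REJECT`` (the default) any symbol outside ``{A, C, G, T}`` raises a
:class:`~seedzip.errors.ValidationError`; under ``STRIP_RECORD`` the
offending symbols are removed and their original 1-based positions are
kept in a *sidecar* list so decompression can reinsert them and remain
lossless.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ValidationError

ALPHABET = frozenset("ACGT")

#: (1-based position in the original uppercased record, removed symbol)
SidecarItem = Tuple[int, str]


class SanitizePolicy(enum.Enum):
    """What to do with symbols outside {A, C, G, T}."""

    REJECT = "reject"
    STRIP_RECORD = "strip-record"


@dataclass(frozen=True)
class DnaSequence:
    """A validated nucleotide string plus its record identifier.

    ``sidecar`` records symbols removed under the strip policy as
    ``(position, symbol)`` pairs in coordinates of the original record,
    so that :func:`reinsert_sidecar` restores the raw string exactly.
    """

    symbols: str
    name: str = ""
    sidecar: Tuple[SidecarItem, ...] = field(default=())

    def __post_init__(self) -> None:
        bad = set(self.symbols) - ALPHABET
        if bad:
            pos = next(
                i + 1 for i, s in enumerate(self.symbols) if s not in ALPHABET
            )
            raise ValidationError(
                f"symbol {self.symbols[pos - 1]!r} at position {pos} "
                f"is outside the ACGT alphabet"
            )

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def l(self) -> int:  # noqa: E743 - field name from the coordinate convention
        return len(self.symbols)


def sanitize(
    raw: str,
    policy: SanitizePolicy = SanitizePolicy.REJECT,
    name: str = "",
) -> DnaSequence:
    """Uppercase ``raw`` and enforce the ACGT alphabet.

    Under ``REJECT`` a non-ACGT symbol raises with its 1-based position.
    Under ``STRIP_RECORD`` non-ACGT symbols are removed and recorded in
    the returned sequence's ``sidecar`` so the original string can be
    rebuilt with :func:`reinsert_sidecar`.
    """
    if isinstance(policy, str):
        policy = SanitizePolicy(policy)
    up = raw.upper()
    if all(s in ALPHABET for s in up):
        return DnaSequence(symbols=up, name=name)
    if policy is SanitizePolicy.REJECT:
        pos = next(i + 1 for i, s in enumerate(up) if s not in ALPHABET)
        raise ValidationError(
            f"symbol {up[pos - 1]!r} at position {pos} is outside the ACGT "
            f"alphabet (policy=reject)"
        )
    kept = []
    sidecar = []
    for i, s in enumerate(up):
        if s in ALPHABET:
            kept.append(s)
        else:
            sidecar.append((i + 1, s))
    return DnaSequence(symbols="".join(kept), name=name, sidecar=tuple(sidecar))


def reinsert_sidecar(symbols: str, sidecar: Iterable[SidecarItem]) -> str:
    """Inverse of the strip policy: put removed symbols back in place.

    Sidecar positions refer to the *final* (original) string, so they are
    applied in ascending order.
    """
    out = list(symbols)
    for pos, sym in sorted(sidecar):
        out.insert(pos - 1, sym)
    return "".join(out)


def read_fasta(
    path: str | Path,
    policy: SanitizePolicy = SanitizePolicy.REJECT,
) -> DnaSequence:
    """Read the first record of a FASTA file, sanitized per ``policy``.

    Multi-record files produce a ``UserWarning`` and only the first record
    is used; an empty file or empty first record raises.
    """
    path = Path(path)
    with open(path) as handle:
        records = SeqIO.parse(handle, "fasta")
        first = next(records, None)
        if first is None:
            raise ValidationError(f"{path}: no FASTA records found")
        if next(records, None) is not None:
            warnings.warn(
                f"{path}: multiple FASTA records; compressing only the first "
                f"({first.id})",
                UserWarning,
                stacklevel=2,
            )
    raw = str(first.seq)
    if not raw:
        raise ValidationError(f"{path}: first record {first.id!r} is empty")
    return sanitize(raw, policy=policy, name=first.id)


def write_fasta(seq: DnaSequence, path: str | Path, width: int = 60) -> None:
    """Write a single FASTA record, wrapping sequence lines at ``width``."""
    if width < 1:
        raise ValueError("width must be a positive integer")
    record = SeqRecord(Seq(seq.symbols), id=seq.name or "seq", description="")
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file([record])
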