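"""Order-0 adaptive arithmetic coding over the nucleotide alphabet.

The model is the minimal adaptive one: per-symbol counts over
{A, C, G, T} plus a dedicated end-of-stream symbol, all initialized to 1
and incremented after each coded symbol, halved (rounding up) whenever the
total reaches 2**16.  The coder is a 32-bit low/high range coder with the
classic pending-bit underflow handling.

Streams are self-delimiting: the encoder's flush emits exactly
``pending + 32`` bits, which makes the number of bits the decoder consumes
equal to the number the encoder emitted.  :func:`ac_decode` therefore
reports an exact consumed-bit count, so several streams can be laid
end-to-end in a container and decoded in sequence.
"""

from __future__ import annotations

from typing import List, Tuple

from .errors import ContractViolation, MalformedContainerError

ALPHABET = "ACGT"
_SYMBOL_INDEX = {s: i for i, s in enumerate(ALPHABET)}
_EOS = len(ALPHABET)  # index of the end-of-stream symbol

PRECISION = 32
_TOP = (1 << PRECISION) - 1
_HALF = 1 << (PRECISION - 1)
_QUARTER = 1 << (PRECISION - 2)
_THREE_QUARTERS = 3 * _QUARTER

#: Rescale the adaptive counts when their total reaches this bound.
MAX_TOTAL = 1 << 16


class SymbolModel:
    """Adaptive frequency model over A, C, G, T and end-of-stream."""

    __slots__ = ("counts", "total")

    def __init__(self) -> None:
        self.counts = [1] * (_EOS + 1)
        self.total = _EOS + 1

    def cum_range(self, sym: int) -> Tuple[int, int]:
        lo = sum(self.counts[:sym])
        return lo, lo + self.counts[sym]

    def find(self, target: int) -> Tuple[int, int, int]:
        """Symbol whose cumulative interval contains ``target``."""
        lo = 0
        for sym, c in enumerate(self.counts):
            if target < lo + c:
                return sym, lo, lo + c
            lo += c
        raise MalformedContainerError("arithmetic decoder target out of range")

    def update(self, sym: int) -> None:
        self.counts[sym] += 1
        self.total += 1
        if self.total >= MAX_TOTAL:
            self.counts = [(c + 1) // 2 for c in self.counts]
            self.total = sum(self.counts)


class _Encoder:
    def __init__(self) -> None:
        self.low = 0
        self.high = _TOP
        self.pending = 0
        self.bits: List[str] = []

    def _emit(self, bit: int) -> None:
        self.bits.append("1" if bit else "0")
        if self.pending:
            self.bits.append(("0" if bit else "1") * self.pending)
            self.pending = 0

    def encode(self, model: SymbolModel, sym: int) -> None:
        span = self.high - self.low + 1
        cum_lo, cum_hi = model.cum_range(sym)
        total = model.total
        self.high = self.low + span * cum_hi // total - 1
        self.low = self.low + span * cum_lo // total
        while True:
            if self.high < _HALF:
                self._emit(0)
            elif self.low >= _HALF:
                self._emit(1)
                self.low -= _HALF
                self.high -= _HALF
            elif self.low >= _QUARTER and self.high < _THREE_QUARTERS:
                self.pending += 1
                self.low -= _QUARTER
                self.high -= _QUARTER
            else:
                break
            self.low <<= 1
            self.high = (self.high << 1) | 1

    def flush(self) -> None:
        # One disambiguating bit plus pending, then zero-padding so the
        # total flush is exactly pending + PRECISION bits: the decoder's
        # read-ahead then consumes precisely what was emitted.
        pad = PRECISION - 2
        self.pending += 1
        self._emit(0 if self.low < _QUARTER else 1)
        self.bits.append("0" * pad)


def ac_encode(symbols: str) -> str:
    """Encode a fragment over {A,C,G,T} (possibly empty) to a bit string."""
    enc = _Encoder()
    model = SymbolModel()
    for s in symbols:
        sym = _SYMBOL_INDEX.get(s)
        if sym is None:
            raise ContractViolation(f"symbol {s!r} outside the ACGT alphabet")
        enc.encode(model, sym)
        model.update(sym)
    enc.encode(model, _EOS)
    enc.flush()
    return "".join(enc.bits)


def ac_decode(bits: str, offset: int = 0) -> Tuple[str, int]:
    """Decode one stream starting at ``offset``; return (fragment, consumed).

    ``consumed`` is exactly the number of bits the matching
    :func:`ac_encode` call emitted, so concatenated streams decode in
    sequence.  A truncated stream raises
    :class:`~seedzip.errors.MalformedContainerError`.
    """
    n = len(bits)
    pos = offset
    if n - pos < PRECISION:
        raise MalformedContainerError("arithmetic stream shorter than the register")
    value = int(bits[pos : pos + PRECISION], 2)
    pos += PRECISION

    def next_bit() -> int:
        nonlocal pos
        if pos >= n:
            raise MalformedContainerError("arithmetic stream truncated")
        b = bits[pos]
        pos += 1
        return 1 if b == "1" else 0

    low = 0
    high = _TOP
    model = SymbolModel()
    out: List[str] = []
    while True:
        span = high - low + 1
        total = model.total
        target = ((value - low + 1) * total - 1) // span
        sym, cum_lo, cum_hi = model.find(target)
        high = low + span * cum_hi // total - 1
        low = low + span * cum_lo // total
        while True:
            if high < _HALF:
                pass
            elif low >= _HALF:
                value -= _HALF
                low -= _HALF
                high -= _HALF
            elif low >= _QUARTER and high < _THREE_QUARTERS:
                value -= _QUARTER
                low -= _QUARTER
                high -= _QUARTER
            else:
                break
            low <<= 1
            high = (high << 1) | 1
            value = (value << 1) | next_bit()
        if sym == _EOS:
            break
        model.update(sym)
        out.append(ALPHABET[sym])
    return "".join(out), pos - offset
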