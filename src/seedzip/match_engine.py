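"""Seed scanning and bidirectional repeat extension.

The search walks a k-symbol seed ``S_{a,b}`` along the working sequence;
for each seed it looks for a later k-mer equal to the seed under one of
the four orientation transforms (forward, reverse, complement, reverse
complement).  A hit is grown leftwards first and then rightwards, one
alignment column at a time, tolerating an edit only while

* the running edit count stays within ``floor(log2 n0)`` of the current
  extended-repeat length ``n0`` (the dynamic threshold), and
* the ``lookahead`` symbols beyond the edit match exactly (the
  compression-gain rule; 3 by default).

When the threshold blocks a direction it is only suspended: growth of the
other direction raises ``n0`` and may re-admit an edit.  A failed gain
check closes the direction for good.  Extension also stops at sequence
boundaries and whenever the extended seed and extended repeat would
overlap.
"""

from __future__ import annotations

import enum
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .errors import ContractViolation
from .repeat_model import (
    EditOp,
    MismatchRecord,
    Occurrence,
    RepeatType,
    materialize,
    mismatch_limit,
    variant_transform,
)

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Fixed tie-break order when several transforms match at the same position.
SEARCH_ORDER = (
    RepeatType.EXACT,
    RepeatType.REVERSE,
    RepeatType.COMPLEMENT,
    RepeatType.REVERSE_COMPLEMENT,
)


class Direction(enum.Enum):
    LEFT = -1
    RIGHT = 1


@dataclass(frozen=True)
class ExtendParams:
    """Tunable knobs of the search: seed length, look-ahead, threshold law."""

    k: int = 8
    lookahead: int = 3
    threshold_mode: str = "log2_n0"  # or "log2_log2_n0"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ContractViolation(f"seed length k must be >= 2, got {self.k}")
        if self.lookahead < 1:
            raise ContractViolation("lookahead must be >= 1")
        if self.threshold_mode not in ("log2_n0", "log2_log2_n0"):
            raise ContractViolation(
                f"unknown threshold mode {self.threshold_mode!r}"
            )

    def threshold(self, n0: int) -> int:
        if self.threshold_mode == "log2_n0":
            return mismatch_limit(n0)
        inner = mismatch_limit(n0)
        return mismatch_limit(inner) if inner >= 1 else 0


@dataclass(frozen=True)
class SeedSpan:
    """A 1-based inclusive interval [a, b] of length k = b - a + 1."""

    a: int
    b: int

    def __post_init__(self) -> None:
        if not 1 <= self.a <= self.b:
            raise ContractViolation(f"invalid seed span ({self.a}, {self.b})")

    @property
    def k(self) -> int:
        return self.b - self.a + 1


@dataclass(frozen=True)
class ExtensionResult:
    """Outcome of growing one seed/repeat pair."""

    seed_span: Tuple[int, int]  # (d, q)
    repeat_span: Tuple[int, int]  # (c, p)
    n0: int
    mismatches: Tuple[MismatchRecord, ...]
    rtype: RepeatType


def mismatch_threshold(n0: int) -> int:
    """The dynamic edit cap: floor(log2(n0)) for an extended length n0."""
    return mismatch_limit(n0)


def build_kmer_index(working: str, k: int) -> Dict[str, List[int]]:
    """Map every k-mer of the working sequence to its 1-based start positions."""
    index: Dict[str, List[int]] = {}
    for i in range(len(working) - k + 1):
        index.setdefault(working[i : i + k], []).append(i + 1)
    return index


def find_next_match(
    working: str,
    k: int,
    seed_start: int = 1,
    index: Optional[Dict[str, List[int]]] = None,
) -> Optional[Tuple[SeedSpan, int, RepeatType]]:
    """First (seed, match) pair in scan order, or None.

    Seeds are tried from ``seed_start`` onward; for each seed the smallest
    match position ``i >= b + 1`` wins, with ties between transforms at the
    same ``i`` broken in :data:`SEARCH_ORDER`.  Returns the seed span, the
    match position and the *transform class* of the hit (forward hits are
    reported as EXACT; the tandem/approximate refinement happens after
    extension).
    """
    if k < 2:
        raise ContractViolation(f"seed length k must be >= 2, got {k}")
    l = len(working)
    if l < 2 * k:
        return None
    if index is None:
        index = build_kmer_index(working, k)
    for a in range(seed_start, l - 2 * k + 2):
        b = a + k - 1
        seed = working[a - 1 : b]
        best: Optional[Tuple[int, int, RepeatType]] = None
        for prio, rtype in enumerate(SEARCH_ORDER):
            positions = index.get(variant_transform(seed, rtype))
            if not positions:
                continue
            j = bisect_left(positions, b + 1)
            if j == len(positions):
                continue
            i = positions[j]
            if best is None or (i, prio) < (best[0], best[1]):
                best = (i, prio, rtype)
        if best is not None:
            return SeedSpan(a, b), best[0], best[2]
    return None


# ---------------------------------------------------------------------------
# Alignment core shared by extend() and the dictionary sweep.
# ---------------------------------------------------------------------------


class _State(enum.Enum):
    OPEN = 0
    SUSPENDED = 1
    CLOSED = 2


@dataclass
class _Alignment:
    """Mutable seed/repeat spans plus the edit log, in absolute coordinates."""

    sd: int
    sq: int
    rc: int
    rp: int
    swap: bool
    comp: bool
    m: int = 0
    left_edits: List[Tuple[int, EditOp, Optional[str]]] = field(default_factory=list)
    right_edits: List[Tuple[int, EditOp, Optional[str]]] = field(default_factory=list)

    @property
    def n0(self) -> int:
        return self.rp - self.rc + 1

    def final_mismatches(self) -> Tuple[MismatchRecord, ...]:
        ordered = list(reversed(self.left_edits)) + self.right_edits
        return tuple(
            MismatchRecord(position=pos - self.sd + 1, op=op, base=base)
            for pos, op, base in ordered
        )


def _pair_matches(working: str, spos: int, rpos: int, comp: bool) -> bool:
    x = working[spos - 1]
    if comp:
        x = _COMP[x]
    return x == working[rpos - 1]


def _lookahead_ok(
    working: str,
    spos0: int,
    rpos0: int,
    sstep: int,
    rstep: int,
    count: int,
    comp: bool,
    seed_lo: int,
    seed_hi: int,
) -> bool:
    """True iff ``count`` alignment columns from (spos0, rpos0) match exactly.

    Returns False near a boundary where fewer than ``count`` symbols remain
    on either side (the gain cannot be demonstrated, so the edit is not
    worth paying for).
    """
    l = len(working)
    for t in range(count):
        spos = spos0 + sstep * t
        rpos = rpos0 + rstep * t
        if not (seed_lo <= spos <= seed_hi) or not (1 <= rpos <= l):
            return False
        if not _pair_matches(working, spos, rpos, comp):
            return False
    return True


def gain_check(
    working: str,
    seed_cursor: int,
    repeat_cursor: int,
    direction: Direction,
    lookahead: int = 3,
    rtype: RepeatType = RepeatType.EXACT,
) -> bool:
    """Would substituting at (seed_cursor, repeat_cursor) pay off?

    The cursors point at the mismatching pair; the check passes iff the
    next ``lookahead`` symbols beyond it (in ``direction``, under the
    occurrence's transform) match exactly and the sequence does not run
    out first.
    """
    sstep = direction.value
    rstep = -sstep if rtype.is_reversed else sstep
    return _lookahead_ok(
        working,
        seed_cursor + sstep,
        repeat_cursor + rstep,
        sstep,
        rstep,
        lookahead,
        rtype.is_complemented,
        1,
        len(working),
    )


def _spans_disjoint(s_lo: int, s_hi: int, r_lo: int, r_hi: int) -> bool:
    return s_hi < r_lo or r_hi < s_lo


def _attempt_column(
    working: str,
    al: _Alignment,
    direction: Direction,
    params: ExtendParams,
    seed_lo: int,
    seed_hi: int,
    forbid: Tuple[int, int],
    frozen: bool = False,
) -> str:
    """Try to grow the alignment by one column in ``direction`` (seed side).

    Returns "advanced", "suspend" (threshold hit, may reopen later) or
    "closed" (boundary, overlap, or failed gain check).  With ``frozen``
    (sweep mode: the seed span is fixed) the gain-rule look-ahead window is
    truncated at the seed boundary — completing full coverage of the seed
    is what makes the occurrence storable at all, so an edit in the last
    columns only needs the remaining columns to match.
    """
    l = len(working)
    sstep = direction.value
    rstep = -sstep if al.swap else sstep
    s_next = (al.sd - 1) if direction is Direction.LEFT else (al.sq + 1)
    r_next = (al.rc - 1) if rstep < 0 else (al.rp + 1)
    if not (seed_lo <= s_next <= seed_hi) or not (1 <= r_next <= l):
        return "closed"

    def new_spans(consume_seed: bool, consume_repeat: bool):
        sd, sq, rc, rp = al.sd, al.sq, al.rc, al.rp
        if consume_seed:
            sd, sq = (min(sd, s_next), max(sq, s_next))
        if consume_repeat:
            rc, rp = (min(rc, r_next), max(rp, r_next))
        return sd, sq, rc, rp

    def step_ok(consume_seed: bool, consume_repeat: bool) -> bool:
        sd, sq, rc, rp = new_spans(consume_seed, consume_repeat)
        f_lo, f_hi = min(forbid[0], sd), max(forbid[1], sq)
        return _spans_disjoint(f_lo, f_hi, rc, rp)

    def commit(consume_seed: bool, consume_repeat: bool) -> None:
        al.sd, al.sq, al.rc, al.rp = new_spans(consume_seed, consume_repeat)

    if not step_ok(True, True):
        return "closed"

    if _pair_matches(working, s_next, r_next, al.comp):
        commit(True, True)
        return "advanced"

    # Mismatch column: threshold first, then the gain rule.
    if al.m + 1 > params.threshold(al.n0):
        return "suspend"

    la = params.lookahead
    y = working[r_next - 1]
    base = _COMP[y] if al.comp else y
    edits = al.left_edits if direction is Direction.LEFT else al.right_edits

    def la_count(spos0: int) -> int:
        if not frozen:
            return la
        avail = (seed_hi - spos0 + 1) if sstep > 0 else (spos0 - seed_lo + 1)
        return max(0, min(la, avail))

    # Substitution: consume both symbols.
    if _lookahead_ok(
        working, s_next + sstep, r_next + rstep, sstep, rstep,
        la_count(s_next + sstep), al.comp, seed_lo, seed_hi,
    ):
        commit(True, True)
        edits.append((s_next, EditOp.SUBSTITUTION, base))
        al.m += 1
        return "advanced"

    # Insertion: the repeat carries an extra symbol; the seed edge waits.
    if step_ok(False, True) and _lookahead_ok(
        working, s_next, r_next + rstep, sstep, rstep,
        la_count(s_next), al.comp, seed_lo, seed_hi,
    ):
        boundary = al.sd if direction is Direction.LEFT else al.sq + 1
        commit(False, True)
        edits.append((boundary, EditOp.INSERTION, base))
        al.m += 1
        return "advanced"

    # Deletion: a seed symbol has no counterpart in the repeat.
    if step_ok(True, False) and _lookahead_ok(
        working, s_next + sstep, r_next, sstep, rstep,
        la_count(s_next + sstep), al.comp, seed_lo, seed_hi,
    ):
        commit(True, False)
        edits.append((s_next, EditOp.DELETION, None))
        al.m += 1
        return "advanced"

    return "closed"


def _run_alignment(
    working: str,
    al: _Alignment,
    params: ExtendParams,
    seed_lo: int,
    seed_hi: int,
    forbid: Tuple[int, int],
    frozen: bool = False,
) -> None:
    """Grow the alignment to its maximum: left first, then right, reopening
    threshold-suspended directions whenever n0 has grown enough."""
    state = {Direction.LEFT: _State.OPEN, Direction.RIGHT: _State.OPEN}
    while True:
        progressed = False
        for direction in (Direction.LEFT, Direction.RIGHT):
            if (
                state[direction] is _State.SUSPENDED
                and al.m + 1 <= params.threshold(al.n0)
            ):
                state[direction] = _State.OPEN
            while state[direction] is _State.OPEN:
                res = _attempt_column(
                    working, al, direction, params, seed_lo, seed_hi, forbid,
                    frozen=frozen,
                )
                if res == "advanced":
                    progressed = True
                elif res == "suspend":
                    state[direction] = _State.SUSPENDED
                    break
                else:
                    state[direction] = _State.CLOSED
                    break
        if not progressed:
            break


def _forward_label(
    seed_span: Tuple[int, int],
    repeat_span: Tuple[int, int],
    mismatches: Sequence[MismatchRecord],
) -> RepeatType:
    """Refine a forward hit into tandem / exact / approximate."""
    adjacent = repeat_span[0] == seed_span[1] + 1 or seed_span[0] == repeat_span[1] + 1
    if not mismatches:
        return RepeatType.TANDEM if adjacent else RepeatType.EXACT
    return RepeatType.APPROXIMATE


def _final_rtype(
    transform: RepeatType,
    seed_span: Tuple[int, int],
    repeat_span: Tuple[int, int],
    mismatches: Sequence[MismatchRecord],
) -> RepeatType:
    if transform in (RepeatType.EXACT, RepeatType.APPROXIMATE, RepeatType.TANDEM):
        return _forward_label(seed_span, repeat_span, mismatches)
    return transform


def extend(
    working: str,
    seed: SeedSpan,
    match_start: int,
    rtype: RepeatType,
    params: ExtendParams,
) -> ExtensionResult:
    """Grow a seed/match pair to the maximal extended seed and repeat.

    ``match_start`` is the 1-based position whose k-mer equals the seed
    under ``rtype``'s transform.  The returned mismatch positions are in
    final extended-seed coordinates.
    """
    k = seed.k
    if working[match_start - 1 : match_start + k - 1] != variant_transform(
        working[seed.a - 1 : seed.b], rtype
    ):
        raise ContractViolation(
            "match_start does not hold the transformed seed k-mer"
        )
    al = _Alignment(
        sd=seed.a,
        sq=seed.b,
        rc=match_start,
        rp=match_start + k - 1,
        swap=rtype.is_reversed,
        comp=rtype.is_complemented,
    )
    _run_alignment(
        working, al, params, seed_lo=1, seed_hi=len(working),
        forbid=(seed.a, seed.b),
    )
    mismatches = al.final_mismatches()
    seed_span = (al.sd, al.sq)
    repeat_span = (al.rc, al.rp)
    result = ExtensionResult(
        seed_span=seed_span,
        repeat_span=repeat_span,
        n0=al.n0,
        mismatches=mismatches,
        rtype=_final_rtype(rtype, seed_span, repeat_span, mismatches),
    )
    _check_extension(working, result)
    return result


def _check_extension(working: str, res: ExtensionResult) -> None:
    """Invariants every extension must satisfy; cheap, always on."""
    d, q = res.seed_span
    c, p = res.repeat_span
    if not _spans_disjoint(d, q, c, p):
        raise ContractViolation("extended seed and repeat overlap")
    if res.n0 != p - c + 1:
        raise ContractViolation("n0 disagrees with the repeat span")
    if len(res.mismatches) > mismatch_limit(res.n0):
        raise ContractViolation("extension exceeded the mismatch threshold")
    seed_str = working[d - 1 : q]
    occ = Occurrence(
        rtype=res.rtype, position=c, length=res.n0, mismatches=res.mismatches
    )
    if materialize(seed_str, occ) != working[c - 1 : p]:
        raise ContractViolation(
            "recorded edits do not reproduce the excised repeat"
        )


# ---------------------------------------------------------------------------
# Sweep: find further occurrences of an already-extended seed.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnchoredOccurrence:
    """A full-coverage match of an extended seed elsewhere in the sequence."""

    repeat_span: Tuple[int, int]
    n0: int
    mismatches: Tuple[MismatchRecord, ...]
    rtype: RepeatType


def _core_anchors(
    working: str,
    core: str,
    index: Optional[Dict[str, List[int]]] = None,
) -> List[Tuple[int, int, RepeatType]]:
    """All (position, priority, transform) hits of the core k-mer, sorted.

    With a prebuilt k-mer ``index`` of the working sequence the scan is a
    few dictionary lookups; otherwise the string is searched directly.
    """
    seen: Dict[int, Tuple[int, RepeatType]] = {}
    for prio, rtype in enumerate(SEARCH_ORDER):
        key = variant_transform(core, rtype)
        if index is not None:
            for pos in index.get(key, ()):
                if pos not in seen or prio < seen[pos][0]:
                    seen[pos] = (prio, rtype)
            continue
        start = 0
        while True:
            hit = working.find(key, start)
            if hit == -1:
                break
            pos = hit + 1
            if pos not in seen or prio < seen[pos][0]:
                seen[pos] = (prio, rtype)
            start = hit + 1
    return sorted((pos, prio, rtype) for pos, (prio, rtype) in seen.items())


def find_seed_occurrences(
    working: str,
    seed_span: Tuple[int, int],
    core_offset: int,
    k: int,
    params: ExtendParams,
    exclude: Sequence[Tuple[int, int]] = (),
    index: Optional[Dict[str, List[int]]] = None,
) -> List[AnchoredOccurrence]:
    """Every non-overlapping full match of the extended seed ``S_{d,q}``.

    ``core_offset`` is the 0-based offset of the original k-mer seed
    inside the extended seed; its transforms anchor the scan.  A candidate
    qualifies only when the constrained alignment covers the whole
    extended seed and its repeat span overlaps neither the seed span, the
    ``exclude`` spans, nor a previously selected candidate.  Candidates
    are returned left to right.
    """
    d, q = seed_span
    seed_len = q - d + 1
    taken: List[Tuple[int, int]] = [seed_span, *exclude]
    out: List[AnchoredOccurrence] = []

    def conflicts(span: Tuple[int, int]) -> bool:
        return any(not _spans_disjoint(span[0], span[1], lo, hi) for lo, hi in taken)

    # Several anchor cores spread over the extended seed: an occurrence whose
    # edit happens to fall inside one core window still anchors via another.
    offsets = sorted({core_offset, 0, (seed_len - k) // 2, seed_len - k})
    anchors: List[Tuple[int, int, RepeatType, int]] = []
    seen = set()
    for off in offsets:
        core = working[d - 1 + off : d - 1 + off + k]
        for pos, prio, rtype in _core_anchors(working, core, index):
            key = (pos, rtype, off)
            if key not in seen:
                seen.add(key)
                anchors.append((pos, prio, rtype, off))
    anchors.sort()

    for pos, _prio, rtype, off in anchors:
        core_span = (pos, pos + k - 1)
        if conflicts(core_span):
            continue
        al = _Alignment(
            sd=d + off,
            sq=d + off + k - 1,
            rc=pos,
            rp=pos + k - 1,
            swap=rtype.is_reversed,
            comp=rtype.is_complemented,
        )
        _run_alignment(
            working, al, params, seed_lo=d, seed_hi=q, forbid=seed_span,
            frozen=True,
        )
        if (al.sd, al.sq) != (d, q):
            continue  # partial coverage cannot be stored as an edit list
        if al.n0 < k:
            continue
        span = (al.rc, al.rp)
        if conflicts(span):
            continue
        mismatches = al.final_mismatches()
        occ = AnchoredOccurrence(
            repeat_span=span,
            n0=al.n0,
            mismatches=mismatches,
            rtype=_final_rtype(rtype, (d, q), span, mismatches),
        )
        seed_str = working[d - 1 : q]
        rec = Occurrence(occ.rtype, span[0], occ.n0, mismatches)
        if materialize(seed_str, rec) != working[span[0] - 1 : span[1]]:
            raise ContractViolation(
                "recorded edits do not reproduce the swept repeat"
            )
        taken.append(span)
        out.append(occ)
    out.sort(key=lambda o: o.repeat_span[0])
    return out
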