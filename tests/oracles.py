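"""Independent reference implementations used only as test oracles.

``brute_find`` enumerates every (seed, position, transform) combination
directly; ``replay_extend`` replays the documented extension rules with
its own cursor bookkeeping.  Both are deliberately written without
touching seedzip internals beyond the public enums, and use Biopython for
the orientation transforms.
"""

from Bio.Seq import Seq

from seedzip.repeat_model import RepeatType

_ORDER = (
    RepeatType.EXACT,
    RepeatType.REVERSE,
    RepeatType.COMPLEMENT,
    RepeatType.REVERSE_COMPLEMENT,
)
_CM = {"A": "T", "T": "A", "C": "G", "G": "C"}


def transform(fragment: str, rtype: RepeatType) -> str:
    if rtype is RepeatType.REVERSE:
        return fragment[::-1]
    if rtype is RepeatType.COMPLEMENT:
        return str(Seq(fragment).complement())
    if rtype is RepeatType.REVERSE_COMPLEMENT:
        return str(Seq(fragment).reverse_complement())
    return fragment


def brute_find(w: str, k: int, seed_start: int = 1):
    """Exhaustive scan: all seeds x all positions x all transforms."""
    l = len(w)
    if l < 2 * k:
        return None
    for a in range(seed_start, l - 2 * k + 2):
        seed = w[a - 1 : a + k - 1]
        for i in range(a + k, l - k + 2):
            kmer = w[i - 1 : i + k - 1]
            for rtype in _ORDER:
                if kmer == transform(seed, rtype):
                    return a, i, rtype
    return None


def replay_extend(w: str, a: int, b: int, i: int, rtype: RepeatType,
                  lookahead: int = 3):
    """Step-by-step replay of the extension rules.

    Returns (seed_span, repeat_span, n0, edits, final_rtype) where edits
    are (P, kind, base) with kind in {'S', 'I', 'D'} and P in final
    extended-seed coordinates.
    """
    l = len(w)
    k = b - a + 1
    comp = rtype in (RepeatType.COMPLEMENT, RepeatType.REVERSE_COMPLEMENT)
    swap = rtype in (RepeatType.REVERSE, RepeatType.REVERSE_COMPLEMENT)
    sd, sq, rc, rp = a, b, i, i + k - 1
    m = 0
    edits_left, edits_right = [], []
    status = {"L": "open", "R": "open"}

    def eq(spos, rpos):
        s = w[spos - 1]
        return (_CM[s] if comp else s) == w[rpos - 1]

    def thr():
        return (rp - rc + 1).bit_length() - 1

    def disjoint(s1, s2, r1, r2):
        return s2 < r1 or r2 < s1

    def column(dirn):
        nonlocal sd, sq, rc, rp, m
        sstep = -1 if dirn == "L" else 1
        rstep = -sstep if swap else sstep
        sn = sd - 1 if dirn == "L" else sq + 1
        rn = rc - 1 if rstep < 0 else rp + 1
        if not (1 <= sn <= l and 1 <= rn <= l):
            return "closed"
        ns = (min(sd, sn), max(sq, sn))
        nr = (min(rc, rn), max(rp, rn))
        if not disjoint(*ns, *nr):
            return "closed"
        if eq(sn, rn):
            sd, sq = ns
            rc, rp = nr
            return "ok"
        if m + 1 > thr():
            return "thr"

        def la_ok(s0, r0):
            for t in range(lookahead):
                sp, rp_ = s0 + sstep * t, r0 + rstep * t
                if not (1 <= sp <= l and 1 <= rp_ <= l) or not eq(sp, rp_):
                    return False
            return True

        base = _CM[w[rn - 1]] if comp else w[rn - 1]
        log = edits_left if dirn == "L" else edits_right
        if la_ok(sn + sstep, rn + rstep):  # substitution
            sd, sq = ns
            rc, rp = nr
            log.append((sn, "S", base))
            m += 1
            return "ok"
        if disjoint(sd, sq, *nr) and la_ok(sn, rn + rstep):  # insertion
            bpos = sd if dirn == "L" else sq + 1
            rc, rp = nr
            log.append((bpos, "I", base))
            m += 1
            return "ok"
        if disjoint(*ns, rc, rp) and la_ok(sn + sstep, rn):  # deletion
            sd, sq = ns
            log.append((sn, "D", None))
            m += 1
            return "ok"
        return "closed"

    while True:
        progressed = False
        for dirn in ("L", "R"):
            if status[dirn] == "thr" and m + 1 <= thr():
                status[dirn] = "open"
            while status[dirn] == "open":
                res = column(dirn)
                if res == "ok":
                    progressed = True
                else:
                    status[dirn] = res if res == "thr" else "closed"
        if not progressed:
            break

    edits = [
        (pos - sd + 1, kind, base)
        for pos, kind, base in list(reversed(edits_left)) + edits_right
    ]
    if rtype is RepeatType.EXACT:
        adjacent = rc == sq + 1 or sd == rp + 1
        if edits:
            final = RepeatType.APPROXIMATE
        elif adjacent:
            final = RepeatType.TANDEM
        else:
            final = RepeatType.EXACT
    else:
        final = rtype
    return (sd, sq), (rc, rp), rp - rc + 1, edits, final
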