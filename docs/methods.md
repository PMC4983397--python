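# Methods

## The model

`seedzip` is a substitution (dictionary) compressor in the Lempel–Ziv
family, specialized for nucleotide sequences. Its premise is that DNA
redundancy lives in *repeats* — long fragments recurring exactly or with
a few point differences, in any of four orientations (forward, reverse,
complement, reverse complement), sometimes adjacent to their source
(tandem). The compressor removes every repeat it can justify on bit cost
into an offline dictionary built in the same pass, then entropy-codes
what is left. Decompression is a deterministic reverse replay of the
recorded excisions, so losslessness does not depend on the search having
made good decisions — only the compression *ratio* does.

All user-visible coordinates are 1-based and inclusive; `S_{i,j}` denotes
the substring from position `i` to `j` of the current working sequence.

## The search loop

A pass over the working sequence proceeds seed by seed:

- The seed `S_{a,b}` is a `k`-mer, starting at `a = 1`. For each seed,
  match positions `i ≥ b + 1` are scanned left to right; the k-mer at `i`
  matches when it equals the seed under one of the four orientation
  transforms. At equal `i` the tie-break order is fixed:
  forward > reverse > complement > reverse complement. If the seed has no
  match, `(a, b)` advance by one.
- A hit is extended to the left first, then to the right, one alignment
  column at a time, in lockstep (one seed symbol against one repeat
  symbol; for reversed orientations the repeat's far end advances). The
  repeat length `n0` starts at `k` and the mismatch count `m` at 0.
- A mismatch column may be consumed as a substitution, or — when a
  substitution does not re-synchronize — as a single-symbol insertion or
  deletion (tried in that fixed order), subject to two rules:
  - **threshold:** `m + 1 ≤ floor(log2 n0)` with `n0` the repeat length
    at the moment the edit is proposed. When the threshold blocks a
    direction, that direction is only *suspended*: growth of the other
    direction raises `n0` and may re-admit an edit. A direction blocked
    by the gain rule, a boundary or an overlap is closed for good; the
    extension ends when both directions are closed or no progress is
    possible.
  - **gain:** the `lookahead` (default 3) symbols beyond the edit must
    match exactly under the orientation transform. Near a boundary where
    fewer than `lookahead` symbols remain the edit is refused — its gain
    cannot be demonstrated.
- Extension also stops at position 1, at the sequence end, and whenever
  the extended seed and extended repeat would overlap.

The extended seed `S_{d,q}` then anchors a sweep for *all* its other full
occurrences. Anchoring uses several `k`-mer cores spread across the
extended seed (its two ends, its middle, and the original seed), so an
occurrence whose edits fall inside one core window still anchors via
another; each anchor is grown with the same column rules but with the
seed span frozen at `[d, q]`. In this frozen mode the look-ahead window
is truncated at the seed boundary: an edit in the last columns only needs
the remaining columns to match, because completing full coverage is what
makes the occurrence storable at all (an occurrence is recorded as an
edit list against the *whole* seed, so partial matches cannot be stored).

## The commit rule

The published formulation of this family of methods prices every recorded
quantity in bits; `seedzip` applies that price before excising anything.
An occurrence is kept only when it saves bits,

    2·n0  >  ceil(log2 c) + M + ceil(log2 l(i)) + 2 ,

(`M` = its mismatch-triple bits), and the entry commits only when its
occurrences' total gain exceeds the seed-position term `ceil(log2 d)`
(the seed's own 2-bit-per-base vocabulary cost cancels against the bases
its excision removes from the residue). Without this rule, chance 8-mer
matches — of which a random 100 kb sequence has tens of thousands —
would each cost more to record than they save, and the output would
*grow*; with it, a patternless input yields a near-empty dictionary and
stays at the 2-bit entropy bound. Gains are evaluated with the idealized
(model) costs rather than the container's fixed-width costs: the model is
the method's own accounting, and keeping the decision independent of
serialization details makes it stable across container revisions.

Committed occurrences are excised left to right, each position recorded
against the sequence *as it stands at that excision*; the seed is excised
last and its position `d` recorded once. The pass then restarts at
`a = 1` on the shortened sequence; the loop terminates because every
commit strictly shortens the working sequence. When no seed commits, the
residue is arithmetic-coded and the container written.

## Decompression

Entries are replayed in reverse creation order: the seed string is
reinserted at `d`, then its occurrences in reverse excision order, each
materialized by applying the edit triples to the seed (insert before
position P / delete at P / substitute at P, positions ascending) and then
the orientation transform. Finally any sidecar symbols (non-ACGT input
handled under the strip policy) are reinserted and the restored length is
checked against the header; a mismatch raises an integrity error rather
than returning silently wrong output.

## Parameters

| knob | default | meaning |
|------|---------|---------|
| `k` | 8 | seed length, in bases. Short seeds flood the scan with chance matches, long ones miss diverged repeats; 8 matches the seed length of classic DNA local-match tools. |
| `lookahead` | 3 | exact bases required beyond a tolerated edit. Smaller admits unprofitable edits; larger rejects genuinely diverged repeats. |
| `threshold_mode` | `log2_n0` | edit budget law. `log2_log2_n0` is exposed for comparison; it admits far fewer edits and generally compresses worse. |
| non-ACGT policy | `reject` | `strip` removes other IUPAC symbols into the sidecar so real-world records with `N` runs still round-trip exactly. |
| `max_passes` | unlimited | safety bound on dictionary passes; the loop provably terminates without it. |

## The entropy coder

Order-0 adaptive arithmetic coding over {A, C, G, T} plus an end-of-stream
symbol: counts start at 1, increment after each coded symbol, and are
halved (rounding up, staying ≥ 1) when the total reaches 2^16. The range
coder is the classic 32-bit low/high construction with pending-bit
underflow handling. The flush emits exactly `pending + 32` bits, chosen
so the decoder's read-ahead consumes precisely the bits the encoder
emitted — streams are therefore self-delimiting and can be concatenated
in the container, each with a fresh model so entries decode
independently. Order 0 is deliberate: it keeps the measured gains
attributable to the repeat dictionary rather than to a strong context
model.

## Numerical and encoding choices

- `log` in the cost model is read as `ceil(log2(·))` of a positive
  integer, so every field gets an integral bit count; `ceil(log2 1) = 0`.
- The idealized model charges 2 bits per occurrence for the repeat type,
  which cannot distinguish six types; the container spends 3. Likewise
  the model's `log P` position widths are not self-delimiting; the
  container uses fixed widths of `ceil(log2(L_w + 1))` bits against the
  recorded working-sequence length `L_w` of each entry. Losslessness wins
  in the bitstream; the model figure is reported as the analytic
  reference, so `stats` always shows idealized ≤ actual.
- Mismatch triples are canonically fixed-width: per entry,
  `width_P = ceil(log2(l(i) + 2))`, admitting an insertion at position
  `l(i) + 1`. The *minimal* encoding (position in exactly its own bit
  length) exists for display and verification of worked examples and is
  never written to the container. On decode, a dialect flag tolerates a
  redundant base field after a deletion triple.
- Ties and orders are all fixed (transform priority, left-then-right
  extension, substitution > insertion > deletion, left-to-right sweep),
  so compression is fully deterministic: identical input and parameters
  give byte-identical containers. There is no randomness anywhere in the
  compressor.
- Degenerate inputs: sequences shorter than `2k` skip straight to entropy
  coding; the empty sequence yields a dictionary-free container.

## Synthetic fixtures

The generator emulates the one feature of real genomes this method
exploits: interspersed repeat families. A family is a source fragment of
~100 bp in an i.i.d.-uniform background with ~8 copies scattered at
random positions (tandem families adjacent instead), each copy carrying
0–2 random substitutions, in one of the six orientation/type classes.
Copy length and copy number are in the range of the most abundant
mammalian interspersed elements; the mutation load is kept within the
method's own recoverability envelope (count within `floor(log2 length)`,
edits ≥ 4 bp apart and ≥ 4 bp from the copy ends, since the gain rule
demands exact context around every edit).

What the generator does *not* emulate: GC skew and composition bias,
nested and truncated repeat copies, indel divergence between copies,
satellite higher-order structure, and the long-range correlation of real
chromatin. Passing the fixture suite therefore demonstrates correctness
(losslessness, determinism, cost accounting) and repeat recovery under
idealized repeat structure — it does not predict compression ratios on
real loci, where divergence patterns are harsher.

## Known limitations

- The seed scan is an index-assisted linear search re-run after every
  committed entry; worst-case cost grows roughly with (entries × length).
  Suffix-structure or bit-parallel acceleration would drop this but is
  out of scope here.
- Occurrences are matched against the *whole* extended seed; a repeat
  family whose copies are truncated relative to the discovered seed is
  only partially captured (each truncated copy may later seed its own
  entry).
- Single-symbol indels only; multi-base gaps between repeat copies are
  treated as separate repeats.
- One sequence per container; multi-record FASTA uses the first record
  only (with a warning).
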