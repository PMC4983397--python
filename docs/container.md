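# The `.szp` container format (version 1)

A single bit stream, most-significant bit first within each field,
multi-bit integers big-endian. The stream is padded with zero bits to a
byte boundary only at the end of the file. Arithmetic-coded streams are
self-delimiting (their decoder consumes exactly the bits their encoder
emitted), so no length prefixes are needed.

| field | bits | meaning |
|---|---|---|
| magic | 32 | ASCII `SZPC` |
| version | 8 | `1` |
| k | 8 | seed length used by the compressor |
| lookahead | 8 | gain-rule look-ahead |
| threshold mode | 8 | 0 = `log2_n0`, 1 = `log2_log2_n0` |
| sanitize policy | 8 | 0 = reject, 1 = strip-record |
| name length | 16 | record identifier byte count |
| name | 8·len | UTF-8 record identifier |
| sidecar count | 32 | number of stripped non-ACGT symbols |
| — per sidecar item: position | 32 | 1-based position in the restored record |
| — per sidecar item: symbol | 8 | ASCII code of the stripped symbol |
| original length | 32 | restored sequence length, verified on decompression |
| entry count n | 32 | dictionary size |

Then, per dictionary entry (in creation order):

| field | bits | meaning |
|---|---|---|
| L_w | 32 | working-sequence length at entry creation; `W = ceil(log2(L_w+1))` sizes the fields below |
| l(i) | W | extended-seed length |
| seed stream | var | arithmetic-coded extended seed (fresh model, self-delimiting) |
| k(i) | W | occurrence count |

Per occurrence (in excision order):

| field | bits | meaning |
|---|---|---|
| repeat type | 3 | 000 exact, 001 approximate, 010 reverse, 011 complement, 100 reverse complement, 101 tandem |
| position c | W | 1-based start in the working sequence at excision time |
| length n0 | W | symbols excised |
| mismatch count | 6 | number of triples |
| triples | var | canonical `(P, E, S)` triples; `width_P = ceil(log2(l(i)+2))`; P ‖ 2-bit op (00 ins / 01 del / 10 sub) ‖ 2-bit base (A=00 C=01 G=10 T=11, omitted for deletions) |

After the occurrences, the entry closes with:

| field | bits | meaning |
|---|---|---|
| seed position d | W | the entry's own excision position |

After the last entry:

| field | bits | meaning |
|---|---|---|
| parsed stream | var | arithmetic-coded final parsed sequence (fresh model) |
| padding | 0–7 | zero bits to the byte boundary |

Positions and lengths are deliberately fixed-width against `L_w` rather
than the idealized `ceil(log2 P)` widths of the cost model: idealized
widths are not self-delimiting. The `stats` subcommand reports both
accountings side by side.
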