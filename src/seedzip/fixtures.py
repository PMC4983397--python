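"""Deterministic synthetic sequences with known planted repeat structure.

Real genomes owe most of their compressibility to interspersed repeat
families: fragments of ~100 bp and up recurring many times, with a few
point differences between copies.  The generators here emulate exactly
that — a patternless i.i.d. background plus planted, possibly mutated and
orientation-transformed copies of chosen source fragments — so repeat
discovery and compression can be tested against a known ground truth
without external data.

All randomness flows through one explicit integer seed; identical seeds
give identical sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import ContractViolation
from .repeat_model import (
    EditOp,
    MismatchRecord,
    RepeatType,
    apply_edits,
    mismatch_limit,
    variant_transform,
)
from .sequence_io import DnaSequence

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def gen_random(n: int, rng_seed: int) -> DnaSequence:
    """An i.i.d.-uniform sequence of length n; same seed, same sequence."""
    if n < 0:
        raise ContractViolation(f"length must be >= 0, got {n}")
    rng = np.random.default_rng(rng_seed)
    symbols = _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")
    return DnaSequence(symbols=symbols, name=f"random_{rng_seed}_{n}")


@dataclass(frozen=True)
class PlantSpec:
    """One planting instruction: copies of a source span inserted elsewhere.

    ``source_span`` is a 1-based inclusive interval of the base sequence;
    ``target_offset`` the 1-based position the copies are inserted before
    (copies of one spec go in back to back).  ``mutations`` are applied to
    every copy before the orientation transform; a ``base`` of None picks
    a random substitute.  The mutation count must stay within
    ``floor(log2(fragment length))`` so planted repeats remain
    discoverable under the dynamic threshold.
    """

    rtype: RepeatType
    source_span: Tuple[int, int]
    target_offset: int
    mutations: Tuple[Tuple[int, EditOp, Optional[str]], ...] = ()
    copies: int = 1


@dataclass(frozen=True)
class PlantedRepeat:
    """Ground truth for one planted copy, in final coordinates."""

    rtype: RepeatType
    start: int
    length: int
    fragment: str
    mutations: Tuple[MismatchRecord, ...]

    @property
    def end(self) -> int:
        return self.start + self.length - 1


def _mutate(fragment: str, spec: PlantSpec, rng: np.random.Generator) -> Tuple[str, Tuple[MismatchRecord, ...]]:
    records = []
    for off, op, base in spec.mutations:
        if base is None and op is not EditOp.DELETION:
            if op is EditOp.SUBSTITUTION and off <= len(fragment):
                choices = [b for b in "ACGT" if b != fragment[off - 1]]
            else:
                choices = list("ACGT")
            base = choices[int(rng.integers(0, len(choices)))]
        records.append(MismatchRecord(position=off, op=op, base=base))
    records.sort(key=lambda m: m.position)
    return apply_edits(fragment, records), tuple(records)


def plant(
    base: DnaSequence,
    specs: Sequence[PlantSpec],
    rng_seed: int,
) -> Tuple[DnaSequence, List[PlantedRepeat]]:
    """Insert every spec's transformed, mutated copies into the base.

    Returns the new sequence and ground-truth annotations (1-based,
    inclusive, final coordinates).  Specs must name distinct insertion
    points and valid source spans.
    """
    rng = np.random.default_rng(rng_seed)
    n = len(base)
    offsets = [s.target_offset for s in specs]
    if len(set(offsets)) != len(offsets):
        raise ContractViolation("plant specs overlap: duplicate target offsets")
    for spec in specs:
        a, b = spec.source_span
        if not (1 <= a <= b <= n):
            raise ContractViolation(f"source span {spec.source_span} outside the base")
        if not (1 <= spec.target_offset <= n + 1):
            raise ContractViolation(f"target offset {spec.target_offset} outside the base")
        if spec.copies < 1:
            raise ContractViolation("copies must be >= 1")
        frag_len = b - a + 1
        if len(spec.mutations) > mismatch_limit(frag_len):
            raise ContractViolation(
                "mutation count exceeds floor(log2(fragment length)); the "
                "planted repeat would not be recoverable"
            )
    out: List[str] = []
    truth: List[PlantedRepeat] = []
    cursor = 0  # 0-based position in base
    pos = 1  # 1-based position in the output
    for spec in sorted(specs, key=lambda s: s.target_offset):
        chunk = base.symbols[cursor : spec.target_offset - 1]
        out.append(chunk)
        pos += len(chunk)
        a, b = spec.source_span
        source = base.symbols[a - 1 : b]
        for _ in range(spec.copies):
            mutated, records = _mutate(source, spec, rng)
            frag = variant_transform(mutated, spec.rtype)
            truth.append(
                PlantedRepeat(
                    rtype=spec.rtype,
                    start=pos,
                    length=len(frag),
                    fragment=frag,
                    mutations=records,
                )
            )
            out.append(frag)
            pos += len(frag)
        cursor = spec.target_offset - 1
    out.append(base.symbols[cursor:])
    seq = DnaSequence(symbols="".join(out), name=base.name or "planted")
    for t in truth:  # annotations must describe the emitted sequence exactly
        assert seq.symbols[t.start - 1 : t.end] == t.fragment
    return seq, truth


def repeat_family_fixture(
    length: int = 10_000,
    density: float = 0.5,
    rng_seed: int = 0,
    copy_length: int = 100,
    copies_per_family: int = 8,
    max_mutations: int = 2,
    rtypes: Sequence[RepeatType] = (
        RepeatType.EXACT,
        RepeatType.APPROXIMATE,
        RepeatType.REVERSE,
        RepeatType.COMPLEMENT,
        RepeatType.REVERSE_COMPLEMENT,
        RepeatType.TANDEM,
    ),
) -> Tuple[DnaSequence, List[PlantedRepeat]]:
    """A sequence of ~``length`` bp whose planted copies make up ``density``.

    Families mimic interspersed repeats: each has one source fragment of
    ``copy_length`` bp in the background and ``copies_per_family`` copies
    scattered at random positions (tandem families go in adjacent), each
    copy carrying 0..``max_mutations`` random substitutions.  Repeat types
    cycle through ``rtypes`` across families.
    """
    if not 0 <= density < 1:
        raise ContractViolation("density must be in [0, 1)")
    rng = np.random.default_rng(rng_seed)
    planted_total = int(round(length * density))
    n_copies = planted_total // copy_length
    base_len = length - n_copies * copy_length
    base = gen_random(base_len, int(rng.integers(0, 2**31 - 1)))
    if n_copies == 0:
        return base, []
    n_families = max(1, -(-n_copies // copies_per_family))
    gap = 10
    if base_len < n_families * (copy_length + gap) + gap:
        raise ContractViolation("background too short for the requested families")
    specs: List[PlantSpec] = []
    copies_left = n_copies
    source_region_end = n_families * (copy_length + gap)
    # tandem arrays insert at source_region positions; scattered copies start
    # beyond them so target offsets never collide
    free = rng.permutation(np.arange(source_region_end + gap, base_len + 2))
    free_iter = iter(int(x) for x in free)
    for f in range(n_families):
        fam_copies = min(copies_per_family, copies_left)
        if fam_copies == 0:
            break
        copies_left -= fam_copies
        rtype = rtypes[f % len(rtypes)]
        src_start = 1 + f * (copy_length + gap)
        span = (src_start, src_start + copy_length - 1)
        if rtype is RepeatType.TANDEM:
            # a tandem array: copies immediately after their source
            specs.append(
                PlantSpec(
                    rtype=rtype,
                    source_span=span,
                    target_offset=span[1] + 1,
                    mutations=(),
                    copies=fam_copies,
                )
            )
            continue
        for _ in range(fam_copies):
            n_mut = int(rng.integers(0, max_mutations + 1))
            # mutations keep >= 4 bp from the copy ends and from each other:
            # the gain rule demands exact context around every edit, so
            # closer spacing would plant unrecoverable repeats
            while True:
                pos = sorted(
                    int(p)
                    for p in rng.choice(
                        np.arange(4, copy_length - 3), size=n_mut, replace=False
                    )
                )
                if all(b - a >= 4 for a, b in zip(pos, pos[1:])):
                    break
            muts = tuple((p, EditOp.SUBSTITUTION, None) for p in pos)
            specs.append(
                PlantSpec(
                    rtype=rtype,
                    source_span=span,
                    target_offset=next(free_iter),
                    mutations=muts,
                    copies=1,
                )
            )
    return plant(base, specs, int(rng.integers(0, 2**31 - 1)))
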