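import pytest

from conftest import planted_base_coverage
from seedzip.container import parse
from seedzip.errors import ContractViolation
from seedzip.fixtures import (
    PlantSpec,
    gen_random,
    plant,
    repeat_family_fixture,
)
from seedzip.pipeline import compress
from seedzip.repeat_model import EditOp, RepeatType


class TestGenRandom:
    def test_empty(self):
        assert gen_random(0, 1).symbols == ""

    def test_determinism(self):
        assert gen_random(500, 42).symbols == gen_random(500, 42).symbols
        assert gen_random(500, 42).symbols != gen_random(500, 43).symbols

    def test_base_frequencies_are_uniform(self):
        symbols = gen_random(100_000, 7).symbols
        for base in "ACGT":
            assert 0.24 <= symbols.count(base) / len(symbols) <= 0.26

    def test_negative_length_rejected(self):
        with pytest.raises(ContractViolation):
            gen_random(-1, 0)


class TestPlant:
    def test_exact_copy_bookkeeping(self):
        base = gen_random(1000, 3)
        spec = PlantSpec(RepeatType.EXACT, (101, 150), 600)
        seq, truth = plant(base, [spec], rng_seed=0)
        assert len(seq) == 1050
        (t,) = truth
        assert (t.start, t.length) == (600, 50)
        assert seq.symbols[t.start - 1 : t.end] == base.symbols[100:150]

    def test_annotations_describe_the_emitted_sequence(self):
        base = gen_random(2000, 9)
        specs = [
            PlantSpec(RepeatType.REVERSE, (1, 40), 500, copies=2),
            PlantSpec(
                RepeatType.REVERSE_COMPLEMENT,
                (50, 99),
                900,
                mutations=((10, EditOp.SUBSTITUTION, None),),
            ),
            PlantSpec(RepeatType.COMPLEMENT, (120, 170), 1400),
        ]
        seq, truth = plant(base, specs, rng_seed=1)
        assert len(truth) == 4
        for t in truth:
            assert seq.symbols[t.start - 1 : t.end] == t.fragment

    def test_duplicate_offsets_rejected(self):
        base = gen_random(500, 1)
        specs = [
            PlantSpec(RepeatType.EXACT, (1, 30), 100),
            PlantSpec(RepeatType.EXACT, (40, 70), 100),
        ]
        with pytest.raises(ContractViolation, match="overlap"):
            plant(base, specs, 0)

    def test_unrecoverable_mutation_load_rejected(self):
        base = gen_random(500, 1)
        muts = tuple((p, EditOp.SUBSTITUTION, "A") for p in (5, 10, 15, 20, 25, 30))
        with pytest.raises(ContractViolation, match="recoverable"):
            plant(base, [PlantSpec(RepeatType.EXACT, (1, 31), 100, muts)], 0)

    def test_reverse_complement_copy_is_recovered(self):
        base = gen_random(1000, 17)
        spec = PlantSpec(
            RepeatType.REVERSE_COMPLEMENT,
            (201, 260),
            700,
            mutations=((20, EditOp.SUBSTITUTION, None),),
        )
        seq, truth = plant(base, [spec], rng_seed=2)
        assert planted_base_coverage(seq, truth) >= 0.9
        pc = parse(compress(seq))
        rtypes = {
            o.rtype for e in pc.dictionary for o in e.occurrences
        }
        assert rtypes & {RepeatType.REVERSE_COMPLEMENT, RepeatType.APPROXIMATE,
                         RepeatType.EXACT}

    def test_tandem_spec_is_labeled_tandem(self):
        base = gen_random(600, 23)
        spec = PlantSpec(RepeatType.TANDEM, (101, 160), 161, copies=2)
        seq, truth = plant(base, [spec], rng_seed=3)
        assert truth[0].start == 161  # adjacent to its source
        pc = parse(compress(seq))
        rtypes = {o.rtype for e in pc.dictionary for o in e.occurrences}
        assert RepeatType.TANDEM in rtypes


class TestRepeatFamilyFixture:
    def test_density_zero_has_no_truth(self):
        seq, truth = repeat_family_fixture(2000, 0.0, 5)
        assert truth == [] and len(seq) == 2000

    def test_length_and_density_accounting(self):
        seq, truth = repeat_family_fixture(10_000, 0.5, 5)
        planted = sum(t.length for t in truth)
        assert len(seq) == 10_000
        assert planted == pytest.approx(5000, abs=100)

    def test_all_six_types_appear(self):
        _, truth = repeat_family_fixture(10_000, 0.5, 5)
        assert {t.rtype for t in truth} == set(RepeatType)

    def test_truth_fragments_match_emitted_sequence(self):
        seq, truth = repeat_family_fixture(5_000, 0.4, 11)
        for t in truth:
            assert seq.symbols[t.start - 1 : t.end] == t.fragment

    def test_planted_bases_recovered_into_the_dictionary(self):
        # interspersed families, <=2 substitutions per copy, 100 bp copies
        seq, truth = repeat_family_fixture(10_000, 0.5, rng_seed=1)
        assert planted_base_coverage(seq, truth) >= 0.9
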