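"""Base-4 chromosome encoding, the genetic operators' printed substitution
patterns and algebra, selection statistics, and evolution-loop behaviour."""

import numpy as np
import pytest

from dnaga_ksvm import dna_ga
from dnaga_ksvm.dna_ga import Chromosome, GAConfig, ParameterSpec


SPECS3 = [
    ParameterSpec("q", 0.0, 2.0),
    ParameterSpec("C", 50.0, 200.0),
    ParameterSpec("sigma", 0.5, 2.0),
]


def seg_chrom():
    # five segments ("00","11","22","33","01") for a length-10 chromosome
    return Chromosome("0011223301")


class TestEncoding:
    def test_random_chromosome_length_and_determinism(self):
        c1 = dna_ga.random_chromosome(SPECS3, np.random.default_rng(7))
        c2 = dna_ga.random_chromosome(SPECS3, np.random.default_rng(7))
        assert len(c1) == 24
        assert c1.digits == c2.digits

    def test_digit_frequencies_uniform(self, rng):
        spec = [ParameterSpec("x", 0.0, 1.0, gene_length=1)]
        draws = [dna_ga.random_chromosome(spec, rng).digits
                 for _ in range(10_000)]
        for d in "0123":
            assert draws.count(d) / 10_000 == pytest.approx(0.25, abs=0.02)

    def test_decode_bounds(self):
        lo = dna_ga.decode(Chromosome("0" * 24), SPECS3)
        hi = dna_ga.decode(Chromosome("3" * 24), SPECS3)
        assert lo == [0.0, 50.0, 0.5]
        assert hi == [2.0, 200.0, 2.0]

    def test_decode_big_endian(self):
        # "20000000" = 2*4^7 = 32768 of 4^8-1 = 65535 codes on [0, 2]
        (v,) = dna_ga.decode(Chromosome("20000000"),
                             [ParameterSpec("q", 0.0, 2.0)])
        assert v == pytest.approx(2 * 32768 / 65535)
        assert v == pytest.approx(1.0000153, abs=1e-6)

    def test_decode_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dna_ga.decode(Chromosome("012"), SPECS3)

    def test_encode_bounds_round_trip(self):
        assert dna_ga.encode([0.0, 50.0, 0.5], SPECS3).digits == "0" * 24
        assert dna_ga.encode([2.0, 200.0, 2.0], SPECS3).digits == "3" * 24

    def test_encode_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dna_ga.encode([2.5, 100.0, 1.0], SPECS3)

    def test_round_trip_error_within_half_quantization_step(self, rng):
        for _ in range(100):
            values = [
                rng.uniform(s.lower, s.upper) for s in SPECS3
            ]
            back = dna_ga.decode(dna_ga.encode(values, SPECS3), SPECS3)
            for v, b, s in zip(values, back, SPECS3):
                half_step = (s.upper - s.lower) / (s.n_codes - 1) / 2
                assert abs(v - b) <= half_step * (1 + 1e-12)

    def test_decode_never_leaves_interval_exhaustive(self):
        spec = [ParameterSpec("x", -1.5, 2.5, gene_length=6)]
        for v in range(4**6):
            digits = np.base_repr(v, base=4).zfill(6)
            (x,) = dna_ga.decode(Chromosome(digits), spec)
            assert -1.5 <= x <= 2.5


class TestCrossover:
    def test_transformation_swaps_segments(self):
        # R5R4R3R2R1 -> R5R2R3R4R1 after R2 and R4 swap
        out = dna_ga.crossover_transformation(seg_chrom(), 1, 3)
        assert out.digits == "0033221101"

    def test_transformation_self_swap_is_identity(self):
        assert dna_ga.crossover_transformation(seg_chrom(), 2, 2).digits \
            == seg_chrom().digits

    def test_transformation_is_involution(self):
        once = dna_ga.crossover_transformation(seg_chrom(), 0, 4)
        twice = dna_ga.crossover_transformation(once, 0, 4)
        assert twice.digits == seg_chrom().digits

    def test_permutation_replaces_segment(self):
        # R5R4R3R2'R1 with donor "12" into R2
        out = dna_ga.crossover_permutation(seg_chrom(), "12", 3)
        assert out.digits == "0011221201"

    def test_permutation_identity_donor(self):
        assert dna_ga.crossover_permutation(seg_chrom(), "33", 3).digits \
            == seg_chrom().digits

    def test_permutation_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dna_ga.crossover_permutation(seg_chrom(), "123", 3)

    def test_permutation_digits_come_from_the_two_parents(self, rng):
        parent_a = dna_ga.random_chromosome(SPECS3, rng)
        parent_b = dna_ga.random_chromosome(SPECS3, rng)
        bounds = dna_ga.segment_bounds(len(parent_a))
        for idx, (a, b) in enumerate(bounds):
            child = dna_ga.crossover_permutation(
                parent_a, parent_b.digits[a:b], idx
            )
            for pos, d in enumerate(child.digits):
                assert d in (parent_a.digits[pos], parent_b.digits[pos])

    def test_translocation_moves_segment(self):
        # R5R2R4R3R1 after R2 moves between R5 and R4
        out = dna_ga.crossover_translocation(seg_chrom(), 3, 1)
        assert out.digits == "0033112201"

    def test_translocation_to_own_position_is_identity(self):
        assert dna_ga.crossover_translocation(seg_chrom(), 3, 3).digits \
            == seg_chrom().digits

    def test_translocation_preserves_digit_multiset(self, rng):
        for _ in range(50):
            chrom = dna_ga.random_chromosome(SPECS3, rng)
            i, j = rng.integers(0, 5, size=2)
            out = dna_ga.crossover_translocation(chrom, int(i), int(j))
            assert sorted(out.digits) == sorted(chrom.digits)


class TestMutation:
    @pytest.mark.parametrize(
        "op,expected",
        [
            (dna_ga.mutate_reversal, "2301"),   # 0<->2, 1<->3
            (dna_ga.mutate_transition, "1032"),  # 0<->1, 2<->3
            (dna_ga.mutate_exchange, "3210"),    # 0<->3, 1<->2
        ],
    )
    def test_substitution_tables(self, op, expected):
        chrom = Chromosome("0123")
        for pos in range(4):
            chrom = op(chrom, pos)
        assert chrom.digits == expected

    @pytest.mark.parametrize(
        "op", [dna_ga.mutate_reversal, dna_ga.mutate_transition,
               dna_ga.mutate_exchange]
    )
    def test_maps_are_fixed_point_free_involutions(self, op):
        for d in "0123":
            once = op(Chromosome(d), 0)
            assert once.digits != d
            assert op(once, 0).digits == d

    def test_reversal_compose_transition_equals_exchange(self):
        for d in "0123":
            via = dna_ga.mutate_reversal(
                dna_ga.mutate_transition(Chromosome(d), 0), 0
            )
            direct = dna_ga.mutate_exchange(Chromosome(d), 0)
            assert via.digits == direct.digits

    def test_point_mutation_changes_exactly_one_digit(self, rng):
        chrom = Chromosome("00112233")
        out = dna_ga.mutate_point(chrom, 3, rng)
        diffs = [i for i in range(8) if out.digits[i] != chrom.digits[i]]
        assert diffs == [3]

    def test_point_mutation_uniform_over_other_digits(self, rng):
        counts = {"1": 0, "2": 0, "3": 0}
        for _ in range(9999):
            out = dna_ga.mutate_point(Chromosome("0"), 0, rng)
            counts[out.digits] += 1
        for d in counts:
            assert counts[d] / 9999 == pytest.approx(1 / 3, abs=0.02)

    def test_bad_position_rejected(self):
        with pytest.raises(ValueError):
            dna_ga.mutate_reversal(Chromosome("0123"), 7)


class TestOperatorClosure:
    def test_randomized_applications_preserve_length_and_alphabet(self, rng):
        chrom = dna_ga.random_chromosome(SPECS3, rng)
        length = len(chrom)
        for _ in range(2000):
            op = rng.integers(0, 7)
            if op == 0:
                i, j = rng.choice(5, 2, replace=False)
                chrom = dna_ga.crossover_transformation(chrom, int(i), int(j))
            elif op == 1:
                idx = int(rng.integers(0, 5))
                a, b = dna_ga.segment_bounds(length)[idx]
                donor = "".join(
                    dna_ga.ALPHABET[d]
                    for d in rng.integers(0, 4, size=b - a)
                )
                chrom = dna_ga.crossover_permutation(chrom, donor, idx)
            elif op == 2:
                chrom = dna_ga.crossover_translocation(
                    chrom, int(rng.integers(0, 5)), int(rng.integers(0, 5))
                )
            else:
                pos = int(rng.integers(0, length))
                fn = [dna_ga.mutate_reversal, dna_ga.mutate_transition,
                      dna_ga.mutate_exchange,
                      lambda c, p: dna_ga.mutate_point(c, p, rng)][op - 3]
                chrom = fn(chrom, pos)
            assert len(chrom) == length
            assert set(chrom.digits) <= set("0123")


class TestSelection:
    def test_elitism_keeps_the_best(self, rng):
        pop = [Chromosome("0000", fitness=0.0) for _ in range(9)]
        pop.append(Chromosome("3333", fitness=1.0))
        out = dna_ga.select(pop, rng)
        assert out[0].digits == "3333"
        assert len(out) == 10

    def test_equal_fitness_resamples_input_multiset(self, rng):
        pop = [Chromosome(d * 4, fitness=0.5) for d in "0123"]
        out = dna_ga.select(pop, rng)
        assert len(out) == 4
        assert {c.digits for c in out} <= {c.digits for c in pop}

    def test_binary_tournament_win_rate(self, rng):
        # of the four equiprobable pairings, the fitter individual wins 3
        pop = [Chromosome("00", fitness=0.9), Chromosome("33", fitness=0.1)]
        wins = 0
        n_slots = 0
        for _ in range(5000):
            out = dna_ga.select(pop, rng)
            wins += sum(c.digits == "00" for c in out[1:])
            n_slots += len(out) - 1
        assert wins / n_slots == pytest.approx(0.75, abs=0.02)

    def test_unevaluated_population_rejected(self, rng):
        with pytest.raises(ValueError):
            dna_ga.select([Chromosome("0123")], rng)
        with pytest.raises(ValueError):
            dna_ga.select([], rng)


class TestEvolve:
    def test_maximizes_decoded_parameter(self):
        spec = [ParameterSpec("q", 0.0, 2.0)]
        cfg = GAConfig(population_size=20, max_generations=30, seed=11)
        _, (q,), _ = dna_ga.evolve(
            lambda c: dna_ga.decode(c, spec)[0] / 2.0, spec, cfg
        )
        assert q >= 1.99

    def test_single_generation_returns_best_of_initial_population(self):
        spec = [ParameterSpec("x", 0.0, 1.0)]
        fitness = lambda c: dna_ga.decode(c, spec)[0]
        cfg = GAConfig(population_size=10, max_generations=1, seed=3)
        best, _, history = dna_ga.evolve(fitness, spec, cfg)
        assert len(history) == 1
        rng = np.random.default_rng(3)
        init = [dna_ga.random_chromosome(spec, rng) for _ in range(10)]
        assert best.fitness == pytest.approx(
            max(fitness(c) for c in init)
        )

    def test_quadratic_objective_recovered_across_seeds(self):
        spec = [ParameterSpec("x", 0.0, 1.0)]
        hits = 0
        for seed in range(20):
            cfg = GAConfig(population_size=30, max_generations=50, seed=seed)
            _, (x,), _ = dna_ga.evolve(
                lambda c: 1 - (dna_ga.decode(c, spec)[0] - 0.7) ** 2,
                spec, cfg,
            )
            hits += abs(x - 0.7) <= 0.05
        assert hits >= 18

    def test_best_ever_trajectory_non_decreasing(self):
        spec = [ParameterSpec("x", 0.0, 1.0)]
        cfg = GAConfig(population_size=12, max_generations=25, seed=5)
        _, _, history = dna_ga.evolve(
            lambda c: 1 - abs(dna_ga.decode(c, spec)[0] - 0.3), spec, cfg
        )
        best_ever = [rec.best_ever for rec in history]
        assert all(b2 >= b1 for b1, b2 in zip(best_ever, best_ever[1:]))
        gen_best = [rec.best for rec in history]  # elite slot is protected
        assert all(b2 >= b1 for b1, b2 in zip(gen_best, gen_best[1:]))

    def test_same_seed_reproduces_run(self):
        spec = [ParameterSpec("x", 0.0, 1.0)]
        cfg = GAConfig(population_size=10, max_generations=10, seed=21)
        fitness = lambda c: dna_ga.decode(c, spec)[0]
        best1, v1, h1 = dna_ga.evolve(fitness, spec, cfg)
        best2, v2, h2 = dna_ga.evolve(fitness, spec, cfg)
        assert best1.digits == best2.digits
        assert v1 == v2
        assert [(r.generation, r.best) for r in h1] == \
            [(r.generation, r.best) for r in h2]

    def test_non_finite_fitness_rejected(self):
        spec = [ParameterSpec("x", 0.0, 1.0)]
        cfg = GAConfig(population_size=4, max_generations=3, seed=0)
        with pytest.raises(ValueError):
            dna_ga.evolve(lambda c: float("nan"), spec, cfg)

    def test_stall_terminates_before_generation_cap(self):
        spec = [ParameterSpec("x", 0.0, 1.0)]
        cfg = GAConfig(population_size=10, max_generations=500, seed=2,
                       fitness_tolerance=0.5, stall_generations=3)
        _, _, history = dna_ga.evolve(
            lambda c: dna_ga.decode(c, spec)[0], spec, cfg
        )
        assert len(history) < 500


def test_config_from_json_and_validation(tmp_path):
    path = tmp_path / "ga.json"
    path.write_text('{"population_size": 8, "max_generations": 5, "seed": 3}')
    cfg = GAConfig.from_json(str(path))
    assert cfg.population_size == 8
    assert cfg.crossover_prob == 0.8  # defaults fill the rest
    with pytest.raises(ValueError):
        GAConfig(population_size=1)
    with pytest.raises(ValueError):
        GAConfig(mutation_prob=1.5)


def test_history_csv(tmp_path):
    spec = [ParameterSpec("x", 0.0, 1.0)]
    cfg = GAConfig(population_size=6, max_generations=4, seed=1)
    _, _, history = dna_ga.evolve(
        lambda c: dna_ga.decode(c, spec)[0], spec, cfg
    )
    out = tmp_path / "history.csv"
    dna_ga.history_to_csv(history, str(out))
    lines = out.read_text().strip().splitlines()
    assert lines[0] == "generation,best,mean,best_ever"
    assert len(lines) == len(history) + 1
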