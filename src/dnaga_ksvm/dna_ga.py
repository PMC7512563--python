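"""DNA genetic algorithm over base-4 chromosomes.

Individuals are fixed-length strings over the quaternary nucleotide
alphabet, written as digits with the assignment C=0, T=1, A=2, G=3.  A
chromosome concatenates one gene per tuned parameter; each gene is read
big-endian as a base-4 integer and mapped affinely onto the parameter's
search interval.  Evolution uses elitist binary tournament selection, three
biologically inspired crossover operators acting on a five-segment
partition of the chromosome (transformation = swap two segments,
permutation = replace a segment with a donor's, translocation = excise a
segment and reinsert it elsewhere), and four mutation operators acting on
single digits (the reversal / transition / exchange base-substitution maps
plus uniform point mutation).  The loop terminates at a generation cap or
when the best fitness stalls within a tolerance for several consecutive
generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

ALPHABET = "0123"
#: number of contiguous segments the crossover operators act on
N_SEGMENTS = 5

# Single-digit substitution maps.  Reversal flips the functional bit
# (C<->A, T<->G), transition the structural bit (C<->T, A<->G), exchange
# flips both (C<->G, T<->A); each is a fixed-point-free involution and
# reversal o transition = exchange.
REVERSAL_MAP = str.maketrans("0123", "2301")
TRANSITION_MAP = str.maketrans("0123", "1032")
EXCHANGE_MAP = str.maketrans("0123", "3210")


@dataclass(frozen=True)
class ParameterSpec:
    """Search interval and gene resolution for one tuned parameter."""

    name: str
    lower: float
    upper: float
    gene_length: int = 8

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: lower must be < upper")
        if self.gene_length < 1:
            raise ValueError("gene_length must be >= 1")

    @property
    def n_codes(self) -> int:
        return 4**self.gene_length


@dataclass
class Chromosome:
    digits: str
    fitness: float | None = None

    def __post_init__(self):
        if any(d not in ALPHABET for d in self.digits):
            raise ValueError("chromosome digits must be over {0,1,2,3}")

    def __len__(self) -> int:
        return len(self.digits)


@dataclass
class GAConfig:
    """Evolution-loop knobs.

    ``fitness_tolerance`` (delta) stops the loop early once the
    generation-to-generation change in best fitness has stayed below it for
    ``stall_generations`` consecutive generations; a single sub-delta step
    alone halts too eagerly under stochastic fitness.
    """

    population_size: int = 20
    max_generations: int = 30
    crossover_prob: float = 0.8
    mutation_prob: float = 0.02
    fitness_tolerance: float = 1e-4
    stall_generations: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")
        if not 0 <= self.crossover_prob <= 1:
            raise ValueError("crossover_prob must be in [0, 1]")
        if not 0 <= self.mutation_prob <= 1:
            raise ValueError("mutation_prob must be in [0, 1]")
        if self.fitness_tolerance <= 0:
            raise ValueError("fitness_tolerance must be > 0")

    @classmethod
    def from_json(cls, path: str) -> "GAConfig":
        import json

        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# encoding / decoding

def total_length(specs: list[ParameterSpec]) -> int:
    return sum(s.gene_length for s in specs)


def random_chromosome(
    specs: list[ParameterSpec], rng: np.random.Generator
) -> Chromosome:
    if not specs:
        raise ValueError("at least one ParameterSpec is required")
    digits = rng.integers(0, 4, size=total_length(specs))
    return Chromosome("".join(ALPHABET[d] for d in digits))


def decode(chrom: Chromosome, specs: list[ParameterSpec]) -> list[float]:
    """Genes read big-endian base-4, mapped affinely onto each interval."""
    if len(chrom) != total_length(specs):
        raise ValueError(
            f"chromosome length {len(chrom)} != total gene length "
            f"{total_length(specs)}"
        )
    values, pos = [], 0
    for spec in specs:
        gene = chrom.digits[pos : pos + spec.gene_length]
        pos += spec.gene_length
        v = int(gene, 4)
        frac = v / (spec.n_codes - 1)
        values.append(spec.lower + frac * (spec.upper - spec.lower))
    return values


def encode(values: list[float], specs: list[ParameterSpec]) -> Chromosome:
    """Nearest-code quantization; inverse of :func:`decode` up to half a step."""
    if len(values) != len(specs):
        raise ValueError("one value per ParameterSpec is required")
    genes = []
    for value, spec in zip(values, specs):
        if not spec.lower <= value <= spec.upper:
            raise ValueError(
                f"{spec.name}={value} outside [{spec.lower}, {spec.upper}]"
            )
        v = round((value - spec.lower) / (spec.upper - spec.lower)
                  * (spec.n_codes - 1))
        gene = np.base_repr(v, base=4).zfill(spec.gene_length)
        genes.append(gene)
    return Chromosome("".join(genes))


# ---------------------------------------------------------------------------
# selection

def select(
    population: list[Chromosome], rng: np.random.Generator
) -> list[Chromosome]:
    """Elitist binary tournament with replacement.

    The best parent is always copied into slot 0; the remaining slots are
    filled by drawing two individuals (with replacement) and keeping the
    fitter.
    """
    if not population:
        raise ValueError("empty population")
    if any(c.fitness is None for c in population):
        raise ValueError("all fitness values must be computed before selection")
    t = len(population)
    best = max(population, key=lambda c: c.fitness)
    out = [replace(best)]
    for _ in range(t - 1):
        i, j = rng.integers(0, t, size=2)
        a, b = population[i], population[j]
        out.append(replace(a if a.fitness >= b.fitness else b))
    return out


# ---------------------------------------------------------------------------
# crossover — five contiguous segments, remainder digits on the left

def segment_bounds(length: int) -> list[tuple[int, int]]:
    base, rem = divmod(length, N_SEGMENTS)
    bounds, pos = [], 0
    for k in range(N_SEGMENTS):
        size = base + (1 if k < rem else 0)
        bounds.append((pos, pos + size))
        pos += size
    return bounds


def _segments(chrom: Chromosome) -> list[str]:
    return [chrom.digits[a:b] for a, b in segment_bounds(len(chrom))]


def crossover_transformation(
    chrom: Chromosome, seg_i: int, seg_j: int
) -> Chromosome:
    """Swap the positions of two segments."""
    segs = _segments(chrom)
    if not (0 <= seg_i < N_SEGMENTS and 0 <= seg_j < N_SEGMENTS):
        raise ValueError("segment index out of range")
    segs[seg_i], segs[seg_j] = segs[seg_j], segs[seg_i]
    return Chromosome("".join(segs))


def crossover_permutation(
    chrom: Chromosome, donor_segment: str, seg_idx: int
) -> Chromosome:
    """Replace one segment with a donor segment of equal length."""
    segs = _segments(chrom)
    if not 0 <= seg_idx < N_SEGMENTS:
        raise ValueError("segment index out of range")
    if len(donor_segment) != len(segs[seg_idx]):
        raise ValueError(
            f"donor length {len(donor_segment)} != segment length "
            f"{len(segs[seg_idx])}"
        )
    if any(d not in ALPHABET for d in donor_segment):
        raise ValueError("donor segment must be over {0,1,2,3}")
    segs[seg_idx] = donor_segment
    return Chromosome("".join(segs))


def crossover_translocation(
    chrom: Chromosome, seg_idx: int, dest: int
) -> Chromosome:
    """Excise a segment and reinsert it at position ``dest`` (0..4)."""
    segs = _segments(chrom)
    if not 0 <= seg_idx < N_SEGMENTS:
        raise ValueError("segment index out of range")
    if not 0 <= dest < N_SEGMENTS:
        raise ValueError("destination out of range")
    seg = segs.pop(seg_idx)
    segs.insert(dest, seg)
    return Chromosome("".join(segs))


# ---------------------------------------------------------------------------
# mutation

def _substitute(chrom: Chromosome, pos: int, table) -> Chromosome:
    if not 0 <= pos < len(chrom):
        raise ValueError("mutation position out of range")
    d = chrom.digits
    return Chromosome(d[:pos] + d[pos].translate(table) + d[pos + 1:])


def mutate_reversal(chrom: Chromosome, pos: int) -> Chromosome:
    """Flip the functional bit of one base: 0<->2, 1<->3."""
    return _substitute(chrom, pos, REVERSAL_MAP)


def mutate_transition(chrom: Chromosome, pos: int) -> Chromosome:
    """Flip the structural bit of one base: 0<->1, 2<->3."""
    return _substitute(chrom, pos, TRANSITION_MAP)


def mutate_exchange(chrom: Chromosome, pos: int) -> Chromosome:
    """Flip both bits of one base: 0<->3, 1<->2."""
    return _substitute(chrom, pos, EXCHANGE_MAP)


def mutate_point(
    chrom: Chromosome, pos: int, rng: np.random.Generator
) -> Chromosome:
    """Replace one digit with a uniformly chosen different digit."""
    if not 0 <= pos < len(chrom):
        raise ValueError("mutation position out of range")
    d = chrom.digits
    others = [c for c in ALPHABET if c != d[pos]]
    new = others[rng.integers(0, len(others))]
    return Chromosome(d[:pos] + new + d[pos + 1:])


# ---------------------------------------------------------------------------
# evolution loop

@dataclass
class GenerationRecord:
    generation: int
    best: float
    mean: float
    best_ever: float


def _vary(
    chrom: Chromosome,
    population: list[Chromosome],
    config: GAConfig,
    rng: np.random.Generator,
) -> Chromosome:
    """Apply (at most) one crossover operator and per-digit mutation."""
    if rng.random() < config.crossover_prob:
        op = rng.integers(0, 3)
        if op == 0:
            i, j = rng.choice(N_SEGMENTS, size=2, replace=False)
            chrom = crossover_transformation(chrom, int(i), int(j))
        elif op == 1:
            donor = population[rng.integers(0, len(population))]
            seg_idx = int(rng.integers(0, N_SEGMENTS))
            a, b = segment_bounds(len(chrom))[seg_idx]
            chrom = crossover_permutation(chrom, donor.digits[a:b], seg_idx)
        else:
            seg_idx = int(rng.integers(0, N_SEGMENTS))
            dest = int(rng.integers(0, N_SEGMENTS))
            chrom = crossover_translocation(chrom, seg_idx, dest)
    digits = chrom.digits
    mutate = rng.random(len(digits)) < config.mutation_prob
    if mutate.any():
        ops = rng.integers(0, 4, size=len(digits))
        out = Chromosome(digits)
        for pos in np.flatnonzero(mutate):
            pos = int(pos)
            op = ops[pos]
            if op == 0:
                out = mutate_reversal(out, pos)
            elif op == 1:
                out = mutate_transition(out, pos)
            elif op == 2:
                out = mutate_exchange(out, pos)
            else:
                out = mutate_point(out, pos, rng)
        chrom = out
    return Chromosome(chrom.digits)  # fitness reset to None


def evolve(
    fitness_fn,
    specs: list[ParameterSpec],
    config: GAConfig,
) -> tuple[Chromosome, list[float], list[GenerationRecord]]:
    """Run the genetic loop and return the best-ever individual.

    ``fitness_fn`` maps a Chromosome to a finite fitness in [0, 1] (larger
    is better).  The elite copy in slot 0 is exempt from crossover and
    mutation, so the best-ever fitness trajectory is non-decreasing.
    """
    rng = np.random.default_rng(config.seed)
    population = [
        random_chromosome(specs, rng) for _ in range(config.population_size)
    ]
    best_ever: Chromosome | None = None
    history: list[GenerationRecord] = []
    prev_best = None
    stall = 0
    for gen in range(1, config.max_generations + 1):
        for c in population:
            if c.fitness is None:
                f = float(fitness_fn(c))
                if not np.isfinite(f):
                    raise ValueError(
                        f"fitness_fn returned non-finite value {f}"
                    )
                c.fitness = f
        gen_best = max(population, key=lambda c: c.fitness)
        if best_ever is None or gen_best.fitness > best_ever.fitness:
            best_ever = replace(gen_best)
        mean = float(np.mean([c.fitness for c in population]))
        history.append(
            GenerationRecord(gen, gen_best.fitness, mean, best_ever.fitness)
        )
        if gen >= config.max_generations:
            break
        if prev_best is not None:
            if abs(best_ever.fitness - prev_best) < config.fitness_tolerance:
                stall += 1
            else:
                stall = 0
            if stall >= config.stall_generations:
                break
        prev_best = best_ever.fitness
        parents = select(population, rng)
        population = [parents[0]] + [
            _vary(c, parents, config, rng) for c in parents[1:]
        ]
    return best_ever, decode(best_ever, specs), history


def history_to_csv(history: list[GenerationRecord], path: str) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["generation", "best", "mean", "best_ever"])
        for rec in history:
            w.writerow([rec.generation, rec.best, rec.mean, rec.best_ever])
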