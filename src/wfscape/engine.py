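"""Wright-Fisher generation engine.

One discrete, non-overlapping generation is the composition

    pair -> recombine -> mutate -> select

* **pair** — a uniformly random perfect matching of the N individuals;
* **recombine** — each pair produces its two complementary crossover
  products: a crossover mask is built by walking loci 0 .. L-1 and switching
  parental source between loci k and k+1 with probability ``r_k`` (no
  interference), the starting parent chosen with probability 1/2.  Keeping
  both complementary gametes makes the pool size N and conserves per-locus
  allele counts exactly, so with flat fitness the per-locus dynamics is
  *exactly* neutral Wright-Fisher binomial resampling — a sharp test oracle.
* **mutate** — each bit of each gamete flips independently with probability
  mu (bidirectional, recurrent);
* **select** — N offspring are drawn from the pool with replacement, with
  probabilities proportional to fitness ``w(genotype)``.

Without mutation a run stops when all loci are monomorphic (a safety cap of
``DEFAULT_MAX_GENERATIONS`` guarantees termination); with mutation a stopping
generation must be configured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError, DegeneratePopulationError, InvalidParameterError
from .landscapes import FitnessLandscape, as_rng
from .population import Population
from . import stats as _stats

#: Safety cap for mutation-free runs (monomorphism is the real stopping rule).
DEFAULT_MAX_GENERATIONS = 10**6


@dataclass(frozen=True)
class RecombinationMap:
    """L-1 per-interval crossover probabilities.

    ``rates[k]`` is the probability of recombination between loci k and k+1;
    each entry lies in [0, 0.5], where 0.5 means free recombination between
    the flanking loci (fractions above 0.5 are not physical).
    """

    rates: np.ndarray

    def __post_init__(self) -> None:
        rates = np.atleast_1d(np.asarray(self.rates, dtype=float))
        if rates.ndim != 1:
            raise InvalidParameterError("recombination rates must be a 1-D vector")
        if rates.size and (np.any(rates < 0) or np.any(rates > 0.5) or not np.all(np.isfinite(rates))):
            raise InvalidParameterError("recombination rates must lie in [0, 0.5]")
        object.__setattr__(self, "rates", rates)

    @property
    def L(self) -> int:
        return self.rates.size + 1

    @classmethod
    def uniform(cls, L: int, r: float) -> "RecombinationMap":
        """Constant probability r between every pair of consecutive loci."""
        return cls(np.full(max(L - 1, 0), float(r)))

    @classmethod
    def from_file(cls, path, L: "int | None" = None) -> "RecombinationMap":
        """Read a plain-text map: L-1 lines, one probability per line, line k
        giving the rate between loci k-1 and k (1-based lines)."""
        with open(path) as fh:
            lines = [line.strip() for line in fh if line.strip() and not line.startswith("#")]
        try:
            rates = np.array([float(x) for x in lines])
        except ValueError as exc:
            raise InvalidParameterError(f"{path}: non-numeric recombination rate: {exc}") from exc
        if L is not None and rates.size != L - 1:
            raise ConfigError(
                f"{path}: recombination map has {rates.size} lines, expected L-1 = {L - 1}"
            )
        return cls(rates)


@dataclass(frozen=True)
class EngineConfig:
    """Generation-engine parameters.

    mutation_rate
        Per-locus per-gamete flip probability, in [0, 1).
    max_generations
        Stopping generation; required when mutation_rate > 0, otherwise a
        safety cap (default ``DEFAULT_MAX_GENERATIONS``).
    record_interval
        Record statistics every n generations (the final generation is always
        recorded).
    exact_fixation_times
        Track per-locus frequencies every generation so fixation times are
        exact even when record_interval > 1 (extra O(N L) work per
        generation).
    """

    mutation_rate: float = 0.0
    max_generations: "int | None" = None
    record_interval: int = 1
    exact_fixation_times: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.mutation_rate < 1.0):
            raise InvalidParameterError(
                f"mutation rate must lie in [0, 1), got {self.mutation_rate}"
            )
        if self.mutation_rate > 0 and self.max_generations is None:
            raise ConfigError("mutation_rate > 0 requires max_generations")
        if self.max_generations is not None and self.max_generations < 1:
            raise InvalidParameterError("max_generations must be >= 1")
        if self.record_interval < 1:
            raise InvalidParameterError("record_interval must be >= 1")

    @property
    def generation_cap(self) -> int:
        return DEFAULT_MAX_GENERATIONS if self.max_generations is None else self.max_generations


def pair_individuals(pop: Population, rng=None) -> np.ndarray:
    """Uniformly random perfect matching, as an (N/2, 2) array of indices."""
    if pop.N % 2:
        raise InvalidParameterError("pairing requires an even population size")
    rng = as_rng(rng)
    return rng.permutation(pop.N).reshape(-1, 2)


def _crossover_masks(n_pairs: int, rates: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Integer masks: bit l set => gamete 1 takes locus l from parent 2."""
    L = rates.size + 1
    start = rng.integers(0, 2, size=n_pairs, dtype=np.int64)
    if L == 1:
        return start
    switch = rng.random((n_pairs, L - 1)) < rates
    source = np.empty((n_pairs, L), dtype=np.int64)
    source[:, 0] = start
    source[:, 1:] = start[:, None] ^ (np.cumsum(switch, axis=1) & 1)
    return source @ (np.int64(1) << np.arange(L, dtype=np.int64))


def recombine_pair(g1: int, g2: int, rmap: RecombinationMap, rng=None) -> tuple:
    """The two complementary crossover products of one parental pair.

    At every locus the multiset of alleles in the two gametes equals the
    multiset in the two parents.
    """
    rng = as_rng(rng)
    mask = int(_crossover_masks(1, rmap.rates, rng)[0])
    g1, g2 = int(g1), int(g2)
    gamete1 = (g1 & ~mask) | (g2 & mask)
    gamete2 = (g1 & mask) | (g2 & ~mask)
    return gamete1, gamete2


def _recombine_all(
    p1: np.ndarray, p2: np.ndarray, rmap: RecombinationMap, rng: np.random.Generator
) -> np.ndarray:
    """Gamete pool (size N) from paired parent arrays (each size N/2)."""
    masks = _crossover_masks(p1.size, rmap.rates, rng)
    gam1 = (p1 & ~masks) | (p2 & masks)
    gam2 = (p1 & masks) | (p2 & ~masks)
    return np.concatenate([gam1, gam2])


def mutate_pool(gametes: np.ndarray, mu: float, L: int, rng=None) -> np.ndarray:
    """Flip each bit of each gamete independently with probability mu."""
    if not (0.0 <= mu < 1.0):
        raise InvalidParameterError(f"mutation rate must lie in [0, 1), got {mu}")
    gametes = np.asarray(gametes, dtype=np.int64)
    if mu == 0.0:
        return gametes.copy()
    rng = as_rng(rng)
    flips = rng.random((gametes.size, L)) < mu
    flip_masks = flips @ (np.int64(1) << np.arange(L, dtype=np.int64))
    return gametes ^ flip_masks


def select_offspring(
    gametes: np.ndarray, landscape: FitnessLandscape, N: int, rng=None
) -> Population:
    """Sample N offspring from the gamete pool with probabilities
    proportional to fitness.  Gametes with fitness 0 are never sampled."""
    gametes = np.asarray(gametes, dtype=np.int64)
    if gametes.size == 0:
        raise InvalidParameterError("gamete pool is empty")
    rng = as_rng(rng)
    weights = landscape.values[gametes]
    total = weights.sum()
    if total <= 0.0:
        raise DegeneratePopulationError("all gametes in the pool have fitness zero")
    cumulative = np.cumsum(weights)
    draws = rng.random(N) * total
    chosen = np.searchsorted(cumulative, draws, side="right")
    return Population(landscape.L, gametes[chosen])


def step_generation(
    pop: Population,
    landscape: FitnessLandscape,
    rmap: RecombinationMap,
    config: EngineConfig,
    rng=None,
) -> Population:
    """Advance one Wright-Fisher generation (pair, recombine, mutate, select)."""
    if rmap.L != pop.L:
        raise InvalidParameterError(
            f"recombination map is for L={rmap.L} loci, population has L={pop.L}"
        )
    rng = as_rng(rng)
    pairs = rng.permutation(pop.N).reshape(-1, 2)
    p1 = pop.genotypes[pairs[:, 0]]
    p2 = pop.genotypes[pairs[:, 1]]
    pool = _recombine_all(p1, p2, rmap, rng)
    if config.mutation_rate > 0.0:
        pool = mutate_pool(pool, config.mutation_rate, pop.L, rng)
    return select_offspring(pool, landscape, pop.N, rng)


def is_monomorphic(pop: Population) -> bool:
    """True iff every locus is at allele frequency 0 or 1 — equivalently,
    all genotype indices are equal."""
    g = pop.genotypes
    return bool((g == g[0]).all())


@dataclass(frozen=True)
class ReplicateResult:
    """Trajectory, summary and requested population dumps of one replicate."""

    replicate: int
    records: tuple
    summary: _stats.RunSummary
    dumps: dict = field(default_factory=dict)
    final_population: "Population | None" = None


def run_replicate(
    pop: Population,
    landscape: FitnessLandscape,
    rmap: RecombinationMap,
    config: EngineConfig,
    rng=None,
    dump_generations: Sequence[int] = (),
    replicate: int = 0,
) -> ReplicateResult:
    """Iterate generations from ``pop`` until the stopping rule fires.

    Statistics are recorded at generations 0, n, 2n, ... and at the final
    generation.  Without mutation the run stops at monomorphism (or at the
    safety cap); with mutation it stops at ``max_generations``.
    """
    rng = as_rng(rng)
    mu = config.mutation_rate
    n = config.record_interval
    cap = config.generation_cap
    dump_set = set(int(g) for g in dump_generations)

    records = [_stats.record_population(pop, landscape, 0)]
    dumps = {0: pop} if 0 in dump_set else {}
    exact = config.exact_fixation_times
    if exact:
        tracked_gens = [0]
        tracked_freqs = [records[0].allele_frequencies]

    gen = 0
    while gen < cap and not (mu == 0.0 and is_monomorphic(pop)):
        pop = step_generation(pop, landscape, rmap, config, rng)
        gen += 1
        stop = gen >= cap or (mu == 0.0 and is_monomorphic(pop))
        recorded = gen % n == 0 or stop
        if recorded:
            records.append(_stats.record_population(pop, landscape, gen))
        if exact:
            tracked_gens.append(gen)
            tracked_freqs.append(
                records[-1].allele_frequencies if recorded else _stats.allele_frequencies(pop)
            )
        if gen in dump_set:
            dumps[gen] = pop

    fixation = None
    if exact:
        fixation = _stats.fixation_times(tracked_gens, np.vstack(tracked_freqs))
    summary = _stats.summarize_run(records, pop, landscape, fixation)
    return ReplicateResult(replicate, tuple(records), summary, dumps, pop)


def replicate_seed_sequence(master_seed: int, replicate: int, stream: int = 0) -> np.random.SeedSequence:
    """Deterministic per-replicate seed, independent of execution order."""
    return np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(stream), int(replicate)))
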