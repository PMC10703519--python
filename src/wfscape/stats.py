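"""Per-generation and end-of-run population statistics.

Definitions used throughout:

* **mean fitness / fitness variance** — population mean and population
  variance (divisor N, not N-1: the population is the whole object, not a
  sample) of ``w(g)`` over individuals.
* **haplotype diversity** — Gini-Simpson index ``1 - sum_h p_h**2`` over
  multi-locus genotype (haplotype) frequencies; 0 iff monomorphic, at most
  ``1 - 1/N``.  The haplotype *count* is reported alongside.
* **distance to peak** — ``w(global peak) - mean fitness``, clamped at 0;
  a secondary variant uses the best individual instead of the mean.
* **fixation time** — first recorded generation at which a locus sits at
  allele frequency 0 or 1 (exact when the record interval is 1; otherwise
  resolution-limited to recorded generations).  Under recurrent mutation a
  locus can re-polymorphize after touching a boundary; the first touch is
  reported and the re-entry flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landscapes import FitnessLandscape, global_peak
from .population import Population


def allele_frequencies(pop: Population) -> np.ndarray:
    """Frequency of allele 1 at each locus (length-L vector)."""
    bits = (pop.genotypes[:, None] >> np.arange(pop.L, dtype=np.int64)) & 1
    return bits.mean(axis=0)


def fitness_values(pop: Population, landscape: FitnessLandscape) -> np.ndarray:
    return landscape.values[pop.genotypes]


def mean_fitness(pop: Population, landscape: FitnessLandscape) -> float:
    return float(fitness_values(pop, landscape).mean())


def fitness_variance(pop: Population, landscape: FitnessLandscape) -> float:
    return float(fitness_values(pop, landscape).var())


def haplotype_counts(pop: Population) -> tuple:
    """(genotype indices, counts), descending by count then ascending index."""
    genotypes, counts = np.unique(pop.genotypes, return_counts=True)
    order = np.lexsort((genotypes, -counts))
    return genotypes[order], counts[order]


def n_haplotypes(pop: Population) -> int:
    return int(np.unique(pop.genotypes).size)


def haplotype_diversity(pop: Population) -> float:
    """Gini-Simpson index over haplotype frequencies: probability that two
    random individuals carry different multi-locus genotypes (sampling with
    replacement)."""
    _, counts = np.unique(pop.genotypes, return_counts=True)
    p = counts / pop.N
    return float(1.0 - (p * p).sum())


def distance_to_peak(pop: Population, landscape: FitnessLandscape) -> float:
    """Global-peak fitness minus mean population fitness, clamped at 0."""
    _, w_peak = global_peak(landscape)
    return max(0.0, w_peak - mean_fitness(pop, landscape))


def distance_to_peak_best(pop: Population, landscape: FitnessLandscape) -> float:
    """Global-peak fitness minus the best individual fitness, clamped at 0."""
    _, w_peak = global_peak(landscape)
    return max(0.0, w_peak - float(fitness_values(pop, landscape).max()))


@dataclass(frozen=True)
class TrajectoryRecord:
    """Statistics of one population snapshot."""

    generation: int
    mean_fitness: float
    fitness_variance: float
    haplotype_diversity: float
    n_haplotypes: int
    distance_to_peak: float
    distance_to_peak_best: float
    allele_frequencies: np.ndarray


def record_population(pop: Population, landscape: FitnessLandscape, generation: int) -> TrajectoryRecord:
    """Compute all trajectory statistics for one snapshot."""
    w = fitness_values(pop, landscape)
    _, w_peak = global_peak(landscape)
    _, counts = np.unique(pop.genotypes, return_counts=True)
    p = counts / pop.N
    mean_w = float(w.mean())
    return TrajectoryRecord(
        generation=int(generation),
        mean_fitness=mean_w,
        fitness_variance=float(w.var()),
        haplotype_diversity=float(1.0 - (p * p).sum()),
        n_haplotypes=int(counts.size),
        distance_to_peak=max(0.0, w_peak - mean_w),
        distance_to_peak_best=max(0.0, w_peak - float(w.max())),
        allele_frequencies=allele_frequencies(pop),
    )


#: Marker for a locus that never reached a frequency boundary.
UNFIXED = -1


@dataclass(frozen=True)
class FixationResult:
    """Per-locus fixation outcome.

    ``times[b]`` — first recorded generation with frequency 0 or 1
    (:data:`UNFIXED` if never); ``alleles[b]`` — the allele that fixed (0/1,
    :data:`UNFIXED` if none); ``repolymorphized[b]`` — True if the locus was
    polymorphic again at a later recorded generation (possible only with
    recurrent mutation).
    """

    times: np.ndarray
    alleles: np.ndarray
    repolymorphized: np.ndarray


def fixation_times(generations, frequencies) -> FixationResult:
    """Per-locus fixation times from a recorded frequency trajectory.

    Parameters
    ----------
    generations
        Increasing sequence of recorded generation numbers (length T).
    frequencies
        (T, L) array of per-locus allele-1 frequencies at those generations.
    """
    generations = np.asarray(generations)
    freqs = np.atleast_2d(np.asarray(frequencies, dtype=float))
    if freqs.shape[0] != generations.size:
        raise ValueError("frequencies must have one row per recorded generation")
    T, L = freqs.shape
    times = np.full(L, UNFIXED, dtype=np.int64)
    alleles = np.full(L, UNFIXED, dtype=np.int64)
    repoly = np.zeros(L, dtype=bool)
    at_boundary = (freqs <= 0.0) | (freqs >= 1.0)
    for b in range(L):
        hits = np.flatnonzero(at_boundary[:, b])
        if hits.size == 0:
            continue
        first = hits[0]
        times[b] = generations[first]
        alleles[b] = 1 if freqs[first, b] >= 1.0 else 0
        repoly[b] = bool((~at_boundary[first:, b]).any())
    return FixationResult(times, alleles, repoly)


@dataclass(frozen=True)
class RunSummary:
    """End-of-run outcome of a single replicate.

    ``reached_global_peak`` is True when the modal (most common) final
    genotype is the landscape's global peak.
    """

    total_generations: int
    fixation: FixationResult
    final_haplotypes: tuple
    final_mean_fitness: float
    reached_global_peak: bool


def summarize_run(
    records, pop: Population, landscape: FitnessLandscape, fixation: "FixationResult | None" = None
) -> RunSummary:
    """Build a :class:`RunSummary` from the recorded trajectory and the final
    population.  ``fixation`` may be supplied from exact per-generation
    tracking; otherwise it is computed from the recorded snapshots."""
    if fixation is None:
        gens = [r.generation for r in records]
        freqs = np.vstack([r.allele_frequencies for r in records])
        fixation = fixation_times(gens, freqs)
    genotypes, counts = haplotype_counts(pop)
    peak_index, _ = global_peak(landscape)
    return RunSummary(
        total_generations=int(records[-1].generation),
        fixation=fixation,
        final_haplotypes=tuple(zip(genotypes.tolist(), counts.tolist())),
        final_mean_fitness=mean_fitness(pop, landscape),
        reached_global_peak=bool(genotypes[0] == peak_index),
    )
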