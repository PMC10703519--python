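"""Populations and standing genetic variation.

A :class:`Population` is a fixed-size multiset of N haploid genotypes
(integer indices, see :mod:`wfscape.landscapes` for the bit convention).
Two initializers provide standing genetic variation with no initial linkage
disequilibrium — loci are filled independently:

* :func:`init_equal` — every locus polymorphic at the same exact allele-1
  count ``max(1, round_half_up(N*p))``;
* :func:`init_sfs` — per-locus minor-allele counts drawn from a folded
  neutral site frequency spectrum truncated at a genetic-drift threshold
  ``c``.

The drift threshold guards against immediate stochastic loss: an allele
present in ``i`` copies is lost in the first generation with probability
about ``exp(-i)`` (:func:`loss_probability`), so ``c = 3`` keeps that
probability below 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .landscapes import as_rng, _check_loci


@dataclass(frozen=True)
class Population:
    """Fixed-size multiset of N haploid genotypes over L loci.

    N must be even (>= 2): each Wright-Fisher generation pairs all
    individuals for recombination.
    """

    L: int
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        _check_loci(self.L)
        genotypes = np.ascontiguousarray(self.genotypes, dtype=np.int64)
        if genotypes.ndim != 1 or genotypes.size < 2 or genotypes.size % 2:
            raise InvalidParameterError(
                f"population size must be an even integer >= 2, got {genotypes.size}"
            )
        if genotypes.min() < 0 or genotypes.max() >= (1 << self.L):
            raise InvalidParameterError("genotype index out of range for L loci")
        object.__setattr__(self, "genotypes", genotypes)

    @property
    def N(self) -> int:
        return self.genotypes.size


def _check_size(N: int) -> None:
    if not isinstance(N, (int, np.integer)) or N < 2 or N % 2:
        raise InvalidParameterError(f"population size must be even and >= 2, got {N!r}")


def init_equal(N: int, L: int, p: float = 0.5, rng=None) -> Population:
    """Population with every locus at the same exact allele-1 count.

    The count is ``max(1, round_half_up(N*p))`` (guaranteeing polymorphism);
    carrier positions are permuted independently per locus, so there is no
    linkage disequilibrium in expectation.
    """
    _check_size(N)
    _check_loci(L)
    p = float(p)
    if not (0.0 < p < 1.0):
        raise InvalidParameterError(f"equal frequency p must be in (0, 1), got {p}")
    count = max(1, math.floor(N * p + 0.5))
    if count > N - 1:
        raise InvalidParameterError(
            f"round(N*p) = {count} leaves locus monomorphic (N = {N}, p = {p})"
        )
    rng = as_rng(rng)
    genotypes = np.zeros(N, dtype=np.int64)
    for b in range(L):
        carriers = rng.permutation(N)[:count]
        genotypes[carriers] |= np.int64(1) << b
    return Population(L, genotypes)


def folded_sfs_weights(N: int, c: int) -> tuple:
    """Support and probabilities of the folded neutral SFS truncated at c.

    Minor-allele count ``i`` in ``{c, ..., floor(N/2)}`` has weight
    ``1/i + 1/(N-i)``, halved at ``i = N/2`` (where minor and major classes
    coincide), renormalized over the truncated support.
    """
    _check_size(N)
    if not isinstance(c, (int, np.integer)) or c < 1 or c > N // 2:
        raise InvalidParameterError(
            f"drift threshold must satisfy 1 <= c <= floor(N/2) = {N // 2}, got {c!r}"
        )
    support = np.arange(c, N // 2 + 1)
    weights = 1.0 / support + 1.0 / (N - support)
    weights[support == N - support] /= 2.0
    return support, weights / weights.sum()


def sample_folded_sfs_count(N: int, c: int, rng=None, size=None):
    """Draw minor-allele copy count(s) from the truncated folded neutral SFS."""
    support, probs = folded_sfs_weights(N, c)
    rng = as_rng(rng)
    out = rng.choice(support, size=size, p=probs)
    return int(out) if size is None else out


def init_sfs(N: int, L: int, c: int = 3, rng=None) -> Population:
    """Population with per-locus minor-allele counts from the folded neutral
    SFS (threshold ``c``).

    Per locus, independently: draw the minor count ``i``, label the minor
    allele 0 or 1 with probability 1/2, and place the ``i`` copies on
    uniformly chosen individuals without replacement.
    """
    _check_size(N)
    _check_loci(L)
    support, probs = folded_sfs_weights(N, c)
    rng = as_rng(rng)
    genotypes = np.zeros(N, dtype=np.int64)
    for b in range(L):
        i = int(rng.choice(support, p=probs))
        minor_is_one = bool(rng.integers(0, 2))
        carriers = rng.choice(N, size=i, replace=False)
        bit = np.int64(1) << b
        if minor_is_one:
            genotypes[carriers] |= bit
        else:
            mask = np.ones(N, dtype=bool)
            mask[carriers] = False
            genotypes[mask] |= bit
    return Population(L, genotypes)


def loss_probability(i: int) -> float:
    """Approximate probability that an allele present in ``i`` copies is lost
    in the first generation of neutral Wright-Fisher reproduction: ``exp(-i)``
    (the Poisson limit of ``(1 - i/N)**N`` for large N)."""
    if not isinstance(i, (int, np.integer)) or i < 0:
        raise InvalidParameterError(f"copy count must be a nonnegative integer, got {i!r}")
    return math.exp(-i)
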