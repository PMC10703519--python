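"""Fitness landscapes over L biallelic loci.

A genotype is an integer index in ``[0, 2**L)``: bit ``b`` (least significant
bit is ``b = 0``) is the allele (0/1) at locus ``b``.  In bitstring form the
*rightmost* character is locus 0, so ``format(index, f"0{L}b")`` and
``int(bitstring, 2)`` convert back and forth.  This convention is used
uniformly in files, dumps and statistics.

Each generator first builds a *raw score* ``F(g)`` on the scale of selection
coefficients, then maps it to a sampling weight (fitness)

    w(g) = max(0, 1 + F(g)).

With effect sizes on the N(0, 0.01) scale used throughout, ``1 + F`` is almost
surely positive; the clamp handles the extreme tail by marking a genotype
inviable (w = 0, never sampled) instead of rejecting the landscape.

Five classical models are provided:

* **additive** — ``F(g) = sum_b a_b bit_b(g)``, no epistasis;
* **Rough Mount Fuji (RMF)** — additive plus an i.i.d. Gaussian epistatic
  term per genotype, ruggedness tuned by ``sigma_epi / additive effect``;
* **NK** — each locus contributes a random table value indexed by its own
  allele and the alleles of K interacting loci; K tunes ruggedness;
* **Block** — independent House-of-Cards sub-landscapes on B contiguous
  blocks of loci, summed; B tunes ruggedness;
* **House-of-Cards (HoC)** — i.i.d. raw score per genotype, the maximal
  ruggedness limit.

Limiting cases are exact: RMF with ``sigma_epi = 0`` equals additive draw for
draw under a shared seed; NK with ``K = 0`` and Block with ``B = L`` are
additive (all pairwise epistasis circuits vanish on raw scores); Block with
``B = 1`` equals HoC draw for draw; RMF with zero additive contribution is
HoC-distributed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .errors import InvalidParameterError, LandscapeFormatError

#: Hard cap on L for full-table landscapes: 2**25 float64 values (~256 MiB)
#: is the practical memory boundary for a desk tool.
MAX_LOCI = 25

#: Default draw distribution for random effects: Normal(mean 0, sd 0.01),
#: the scale used for both additive and epistatic effects throughout.
DEFAULT_EFFECT_SD = 0.01

Distribution = Callable[[np.random.Generator, int], np.ndarray]


def default_dist(rng: np.random.Generator, size: int) -> np.ndarray:
    """Normal(0, DEFAULT_EFFECT_SD) draws — the default effect distribution."""
    return rng.normal(0.0, DEFAULT_EFFECT_SD, size)


def as_rng(rng: "np.random.Generator | int | np.random.SeedSequence | None") -> np.random.Generator:
    """Coerce a seed / SeedSequence / Generator / None into a Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def to_bitstring(index: int, L: int) -> str:
    """Genotype index -> L-character bitstring (rightmost char = locus 0)."""
    return format(index, f"0{L}b")


def from_bitstring(bits: str) -> int:
    """L-character bitstring (rightmost char = locus 0) -> genotype index."""
    return int(bits, 2)


def bit_matrix(L: int) -> np.ndarray:
    """(2**L, L) matrix: row g, column b = allele of genotype g at locus b."""
    idx = np.arange(1 << L, dtype=np.int64)
    return (idx[:, None] >> np.arange(L, dtype=np.int64)) & 1


def _check_loci(L: int) -> None:
    if not isinstance(L, (int, np.integer)) or L < 1 or L > MAX_LOCI:
        raise InvalidParameterError(
            f"locus count L must be an integer in [1, {MAX_LOCI}], got {L!r}"
        )


def raw_to_fitness(raw: np.ndarray) -> np.ndarray:
    """Map raw scores F(g) to sampling weights w(g) = max(0, 1 + F(g))."""
    return np.maximum(0.0, 1.0 + np.asarray(raw, dtype=float))


@dataclass(frozen=True)
class FitnessLandscape:
    """Complete fitness table over all ``2**L`` genotypes.

    Parameters
    ----------
    L
        Number of biallelic loci, ``1 <= L <= MAX_LOCI``.
    values
        Fitness (sampling weight) per genotype index; nonnegative, finite,
        length ``2**L``.
    meta
        Provenance: model name, parameters, seed — echoed into output files.
    raw_scores
        Optional model-scale raw scores ``F(g)`` with
        ``values = max(0, 1 + raw_scores)``; ``None`` for user tables.
    """

    L: int
    values: np.ndarray
    meta: dict = field(default_factory=dict)
    raw_scores: "np.ndarray | None" = None

    def __post_init__(self) -> None:
        _check_loci(self.L)
        values = np.ascontiguousarray(self.values, dtype=float)
        if values.shape != (1 << self.L,):
            raise InvalidParameterError(
                f"landscape over L={self.L} loci needs {1 << self.L} values, "
                f"got shape {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise InvalidParameterError("fitness values must all be finite")
        if np.any(values < 0):
            raise InvalidParameterError("fitness values must all be >= 0")
        object.__setattr__(self, "values", values)
        if self.raw_scores is not None:
            raw = np.ascontiguousarray(self.raw_scores, dtype=float)
            if raw.shape != values.shape:
                raise InvalidParameterError("raw_scores must match values in length")
            object.__setattr__(self, "raw_scores", raw)

    @property
    def n_genotypes(self) -> int:
        return 1 << self.L

    def fitness(self, genotypes: np.ndarray) -> np.ndarray:
        """Fitness of an array of genotype indices."""
        return self.values[np.asarray(genotypes)]


def _additive_effects(
    L: int,
    effect: "float | Sequence[float] | None",
    effect_sd: "float | None",
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-locus additive effects: a constant, an explicit vector, or i.i.d.
    Normal(0, effect_sd) draws.  Exactly one of effect / effect_sd applies;
    if neither is given, effects are drawn with sd DEFAULT_EFFECT_SD."""
    if effect is not None and effect_sd is not None:
        raise InvalidParameterError("give either 'effect' or 'effect_sd', not both")
    if effect is not None:
        a = np.asarray(effect, dtype=float)
        if a.ndim == 0:
            a = np.full(L, float(a))
        elif a.shape != (L,):
            raise InvalidParameterError(
                f"per-locus effect vector must have length L={L}, got {a.shape}"
            )
        return a
    sd = DEFAULT_EFFECT_SD if effect_sd is None else float(effect_sd)
    if sd < 0:
        raise InvalidParameterError(f"effect_sd must be >= 0, got {sd}")
    return rng.normal(0.0, sd, L)


def gen_additive(
    L: int,
    effect: "float | Sequence[float] | None" = None,
    effect_sd: "float | None" = None,
    rng=None,
) -> FitnessLandscape:
    """Additive landscape: ``F(g) = sum_b a_b bit_b(g)`` — zero epistasis.

    ``effect`` is a constant applied to every locus (or an explicit length-L
    vector); alternatively ``effect_sd`` draws each ``a_b`` from
    Normal(0, effect_sd).  Default: draws with sd ``DEFAULT_EFFECT_SD``.
    """
    _check_loci(L)
    rng = as_rng(rng)
    a = _additive_effects(L, effect, effect_sd, rng)
    raw = bit_matrix(L) @ a
    meta = {"model": "additive", "loci": L, "effects": a.tolist()}
    return FitnessLandscape(L, raw_to_fitness(raw), meta, raw)


def gen_rmf(
    L: int,
    sigma_epi: float,
    effect: "float | Sequence[float] | None" = None,
    effect_sd: "float | None" = None,
    rng=None,
) -> FitnessLandscape:
    """Rough Mount Fuji landscape: additive part plus an independent
    Normal(0, sigma_epi) epistatic term per genotype.

    ``sigma_epi = 0`` reproduces :func:`gen_additive` exactly under the same
    seed; a zero additive part gives House-of-Cards behavior.  Ruggedness is
    quantified by :func:`ruggedness_rmf`.
    """
    _check_loci(L)
    sigma_epi = float(sigma_epi)
    if sigma_epi < 0:
        raise InvalidParameterError(f"sigma_epi must be >= 0, got {sigma_epi}")
    rng = as_rng(rng)
    a = _additive_effects(L, effect, effect_sd, rng)
    raw = bit_matrix(L) @ a + rng.normal(0.0, sigma_epi, 1 << L)
    meta = {"model": "rmf", "loci": L, "sigma_epi": sigma_epi, "effects": a.tolist()}
    return FitnessLandscape(L, raw_to_fitness(raw), meta, raw)


def _nk_neighbors(L: int, K: int, scheme: str, rng: np.random.Generator) -> list:
    if scheme == "adjacent":
        return [[(b + j) % L for j in range(1, K + 1)] for b in range(L)]
    if scheme == "random":
        others = [[x for x in range(L) if x != b] for b in range(L)]
        return [sorted(rng.choice(others[b], size=K, replace=False).tolist()) for b in range(L)]
    raise InvalidParameterError(f"nk scheme must be 'adjacent' or 'random', got {scheme!r}")


def gen_nk(
    L: int,
    K: int,
    scheme: str = "adjacent",
    dist: "Distribution | None" = None,
    rng=None,
) -> FitnessLandscape:
    """NK landscape: locus ``b`` contributes a table value indexed by its own
    allele and the alleles of its K interacting loci; the raw score is the
    mean of the L contributions (so its scale does not grow with L).

    ``scheme='adjacent'`` interacts with the K circularly following loci;
    ``scheme='random'`` draws K distinct non-self partners per locus with the
    supplied generator.  ``K = 0`` is the additive limit; ``K = L - 1`` the
    House-of-Cards-like maximal-ruggedness limit.
    """
    _check_loci(L)
    if not (0 <= K <= L - 1):
        raise InvalidParameterError(f"K must satisfy 0 <= K <= L-1 = {L - 1}, got {K}")
    rng = as_rng(rng)
    dist = dist or default_dist
    neighbors = _nk_neighbors(L, K, scheme, rng)
    tables = np.asarray(dist(rng, L << (K + 1)), dtype=float).reshape(L, 1 << (K + 1))
    idx = np.arange(1 << L, dtype=np.int64)
    raw = np.zeros(1 << L)
    for b in range(L):
        state = (idx >> b) & 1
        for j, nb in enumerate(neighbors[b]):
            state = state | (((idx >> nb) & 1) << (j + 1))
        raw += tables[b][state]
    raw /= L
    meta = {"model": "nk", "loci": L, "K": K, "scheme": scheme, "neighbors": neighbors}
    return FitnessLandscape(L, raw_to_fitness(raw), meta, raw)


def _block_sizes(L: int, B: int) -> list:
    base, rem = divmod(L, B)
    return [base + 1] * rem + [base] * (B - rem)


def gen_block(
    L: int,
    B: int,
    dist: "Distribution | None" = None,
    rng=None,
) -> FitnessLandscape:
    """Block landscape: loci are partitioned into B contiguous blocks of
    near-equal size (sizes differ by at most 1, larger blocks first, starting
    at locus 0); each block carries an independent House-of-Cards
    sub-landscape over its sub-genotype and the raw score is the sum of block
    values.

    ``B = L`` reduces exactly to an additive model with random per-allele
    effects; ``B = 1`` equals :func:`gen_hoc` draw for draw.
    """
    _check_loci(L)
    if not (1 <= B <= L):
        raise InvalidParameterError(f"B must satisfy 1 <= B <= L = {L}, got {B}")
    rng = as_rng(rng)
    dist = dist or default_dist
    sizes = _block_sizes(L, B)
    idx = np.arange(1 << L, dtype=np.int64)
    raw = np.zeros(1 << L)
    start = 0
    for size in sizes:
        table = np.asarray(dist(rng, 1 << size), dtype=float)
        raw += table[(idx >> start) & ((1 << size) - 1)]
        start += size
    meta = {"model": "block", "loci": L, "B": B, "block_sizes": sizes}
    return FitnessLandscape(L, raw_to_fitness(raw), meta, raw)


def gen_hoc(L: int, dist: "Distribution | None" = None, rng=None) -> FitnessLandscape:
    """House-of-Cards landscape: i.i.d. raw score per genotype — statistically
    independent fitness values, the maximal-ruggedness limit."""
    _check_loci(L)
    rng = as_rng(rng)
    dist = dist or default_dist
    raw = np.asarray(dist(rng, 1 << L), dtype=float)
    meta = {"model": "hoc", "loci": L}
    return FitnessLandscape(L, raw_to_fitness(raw), meta, raw)


def landscape_from_table(rows: Iterable) -> FitnessLandscape:
    """Build a landscape from ``(bitstring, fitness)`` rows.

    Exactly ``2**L`` rows, one per genotype, all bitstrings of equal length L
    (rightmost character = locus 0), all fitness values finite and >= 0.
    """
    rows = list(rows)
    if not rows:
        raise LandscapeFormatError("empty landscape table")
    L = len(str(rows[0][0]))
    if L < 1 or L > MAX_LOCI:
        raise LandscapeFormatError(
            f"bitstring length must be in [1, {MAX_LOCI}], got {L}"
        )
    values = np.full(1 << L, np.nan)
    for bits, fit in rows:
        bits = str(bits)
        if len(bits) != L or any(c not in "01" for c in bits):
            raise LandscapeFormatError(
                f"inconsistent or invalid genotype bitstring {bits!r} "
                f"(expected {L} characters of 0/1)"
            )
        index = from_bitstring(bits)
        if not np.isnan(values[index]):
            raise LandscapeFormatError(f"duplicate genotype {bits!r}")
        fit = float(fit)
        if not np.isfinite(fit):
            raise InvalidParameterError(f"non-finite fitness for genotype {bits!r}")
        if fit < 0:
            raise InvalidParameterError(f"negative fitness {fit} for genotype {bits!r}")
        values[index] = fit
    if np.isnan(values).any():
        missing = int(np.isnan(values).argmax())
        raise LandscapeFormatError(
            f"missing genotype {to_bitstring(missing, L)!r}: "
            f"expected {1 << L} rows, got {len(rows)}"
        )
    return FitnessLandscape(L, values, {"model": "custom", "loci": L})


def write_landscape_csv(landscape: FitnessLandscape, path) -> None:
    """Write ``genotype,fitness`` CSV in ascending genotype-index order.

    Fitness values are written with full float repr, so a read back through
    :func:`read_landscape_csv` round-trips bit-exactly.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["genotype", "fitness"])
        for index, value in enumerate(landscape.values):
            writer.writerow([to_bitstring(index, landscape.L), repr(float(value))])


def read_landscape_csv(path) -> FitnessLandscape:
    """Read a ``genotype,fitness`` CSV written by :func:`write_landscape_csv`
    (or user-authored in the same format)."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[:2]] != ["genotype", "fitness"]:
            raise LandscapeFormatError(
                f"{path}: expected header 'genotype,fitness', got {header!r}"
            )
        rows = [(row[0].strip(), row[1]) for row in reader if row]
    return landscape_from_table(rows)


def global_peak(landscape: FitnessLandscape) -> tuple:
    """(genotype index, fitness) of the global fitness maximum; ties are
    broken toward the lowest genotype index."""
    index = int(np.argmax(landscape.values))
    return index, float(landscape.values[index])


def ruggedness_rmf(sigma_epi: float, additive_effect: float) -> float:
    """RMF ruggedness: ratio of the epistatic standard deviation to the
    (constant, positive) additive effect.  0 = smooth/additive; larger values
    mean epistasis dominates."""
    sigma_epi = float(sigma_epi)
    additive_effect = float(additive_effect)
    if sigma_epi < 0:
        raise InvalidParameterError(f"sigma_epi must be >= 0, got {sigma_epi}")
    if additive_effect <= 0:
        raise InvalidParameterError(
            f"additive_effect must be > 0, got {additive_effect}"
        )
    return sigma_epi / additive_effect
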