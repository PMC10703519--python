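# Methods

## Reproduction model

Each generation of a population of N haploid individuals (N even, constant)
is the composition *pair → recombine → mutate → select*.

**Pairing.** A uniform random permutation of the N individuals, read off in
consecutive pairs, yields a uniformly distributed perfect matching.

**Recombination.** For each pair a crossover mask over the L loci is built
by a Markov walk: the source parent of locus 0 is chosen with probability
1/2, and the source switches between loci k and k+1 with probability r_k
(independent Bernoulli switches, i.e. no crossover interference). The pair
contributes *both* complementary products (mask and complement) to the
gamete pool. Consequences of keeping both products:

* the pool has exactly N gametes;
* per-locus allele counts in the pool equal those among the parents, so the
  only stochastic change in allele frequency per generation comes from the
  selection step. With flat fitness, the offspring count of an allele at
  frequency p is exactly Binomial(N, p): the model is *exactly* neutral
  Wright-Fisher per locus, which gives sharp closed-form test oracles
  (heterozygosity decay (1−1/N)^t, fixation probability = initial
  frequency, one-generation loss (1−i/N)^N ≈ e^(−i)).

Map entries are restricted to [0, 0.5]; 0.5 decouples the flanking loci.
Odd population sizes are rejected at construction time — pairing is total.

**Mutation.** After recombination, each of the N·L gamete bits flips
independently with probability μ (0→1 and 1→0 symmetric, recurrent). μ = 0
skips the step entirely.

**Selection.** N draws with replacement from the pool, each gamete weighted
by its fitness. Implemented by inversion sampling on the cumulative weight
vector; zero-weight (inviable) gametes occupy zero-length intervals and are
never chosen. If every gamete has weight zero the run aborts with a
degenerate-population error rather than silently recycling the parents.

**Stopping.** Without mutation, frequencies 0 and 1 are absorbing, so the
run stops at monomorphism (all genotype indices equal); a safety cap of
10⁶ generations guarantees termination on (near-)neutral landscapes. With
mutation, boundaries are not absorbing and a `max_generations` stopping
generation is required.

## Fitness landscapes

Genotypes are integers in [0, 2^L); bit b (least significant = b 0) is the
allele at locus b; in bitstring files the rightmost character is locus 0.
One convention everywhere — files, dumps, statistics.

Models define a raw score F(g) on the scale of selection coefficients:

* **additive** — F(g) = Σ_b a_b·bit_b(g); effects a_b are a user constant,
  an explicit vector, or i.i.d. Normal(0, s_a) draws;
* **RMF** — additive plus ε(g) ~ Normal(0, σ²) i.i.d. per genotype;
  ruggedness ≔ σ / a for constant a > 0;
* **NK** — locus b contributes f_b(state), state = alleles of b and its K
  interaction partners; contributions are i.i.d. table entries; the raw
  score is the *mean* over loci, keeping the scale independent of L.
  Neighborhoods are circularly adjacent by default, or K distinct random
  non-self partners per locus (drawn once with the landscape seed);
* **Block** — contiguous blocks of near-equal size (sizes differ by ≤ 1,
  larger blocks first from locus 0), each carrying an independent
  House-of-Cards table over its sub-genotype; the raw score is the *sum* of
  block values, which makes B = L reduce exactly to an additive model and
  B = 1 identical (draw for draw) to House-of-Cards;
* **HoC** — F(g) i.i.d. per genotype.

The default effect distribution everywhere is Normal(mean 0, sd 0.01),
matching the scale on which the simulator is normally exercised.

**Fitness transform.** Sampling weights must be nonnegative, so
w(g) = max(0, 1 + F(g)). With sd-0.01-scale effects, 1 + F is almost surely
positive; the clamp marks extreme-tail genotypes inviable (never sampled)
instead of rejecting the landscape. The transform is this package's own
choice among the reasonable options (exponentiation, offset, rejection);
it is linear where it matters, so F is directly a selection coefficient.

Limiting-case equivalences (RMF σ=0 ≡ additive; NK K=0 and Block B=L
additive; Block B=1 ≡ HoC) are exact under shared seeds and are enforced by
tests via brute-force epistasis circuits F(g)+F(g⊕m₁⊕m₂)−F(g⊕m₁)−F(g⊕m₂)
and Hamming-neighbor correlations over replicate landscapes.

Full tables cap L at 25 (2^25 float64 values ≈ 256 MiB).

## Standing genetic variation

Loci are initialized independently — no linkage disequilibrium.

* **equal mode** — every locus carries exactly max(1, round-half-up(N·p))
  copies of allele 1 (p defaults to 0.5), at per-locus permuted positions.
  The floor of 1 and round-half-up guarantee polymorphism; a count reaching
  N is rejected.
* **SFS mode** — the minor-allele count i of each locus is drawn from the
  folded neutral site frequency spectrum, weight 1/i + 1/(N−i) on
  i ∈ {c, …, ⌊N/2⌋}, halved at i = N/2 (minor and major classes coincide),
  renormalized after truncation at the drift threshold c. Truncation (not
  rejection-resampling) is the threshold semantics: its purpose is to avoid
  alleles so rare that drift removes them before selection acts, motivated
  by the one-generation loss probability e^(−i) (< 0.05 for i ≥ 3). The
  minor allele is labeled 0 or 1 with probability 1/2, so initialization is
  unbiased with respect to the landscape.

## Statistics

* allele frequencies — per-locus popcount / N;
* mean fitness and fitness variance — population moments (divisor N);
* haplotype diversity — Gini-Simpson 1 − Σ p_h² over genotype frequencies
  (bounded by 1 − 1/N; 0 iff monomorphic); the haplotype count is emitted
  alongside since "diversity" is sometimes read as richness;
* distance to the global peak — w(peak) − mean fitness, clamped at 0; a
  secondary column uses the best individual instead of the mean;
* fixation times — first *recorded* generation at a frequency boundary,
  exact when the record interval n = 1 or when per-generation tracking
  (`exact_fixation_times`) is enabled; under mutation a later return to
  polymorphism is flagged, and the first touch is reported;
* run summary — total generations, per-locus fixation outcome, final
  haplotype counts, final mean fitness, and whether the modal final
  genotype is the global peak.

Distance to the peak is *not* monotone on rugged landscapes (valleys), so
only nonnegativity and the terminal identity are asserted.

## Randomness and reproducibility

All randomness flows through numpy PCG64 generators. A run derives one
stream per concern from integer seeds via `SeedSequence(entropy, spawn_key)`:
landscape (master or explicit `landscape_seed`), per-replicate
initialization (spawn key (1, k)), per-replicate generations (spawn key
(2, k)). Replicate k's streams depend only on k, never on a shared
sequential stream, so results are independent of execution order and
replicate subsets are reproducible. Identical config + seeds give
bit-identical trajectories and files; output headers echo the config,
seeds and version.

## Numerical choices

* Genotypes are bit-packed int64 scalars; whole-population operations are
  vectorized numpy (crossover masks via cumulative XOR parity of switch
  indicators, selection via searchsorted on cumulative weights). One
  generation at N = 10⁴, L = 10 costs ~2 ms on one core.
* Global-peak ties break to the lowest genotype index (deterministic).
* Fitness CSV values are written with full float repr for bit-exact
  round-trips.
* Population dumps aggregate to (genotype, count): individuals are
  exchangeable, counts are lossless.

## What the tests show — and what they do not

The synthetic study conditions mirror the regimes the simulator is built
for: effect sizes ~ N(0, 0.01), populations 10²–10⁴, 1–15 loci, uniform
r ∈ [0, 0.5], SFS threshold 3. End-to-end checks use closed-form neutral
and single-locus-selection oracles (heterozygosity decay, fixation
probabilities including the diffusion approximation
(1−e^(−2Nsp))/(1−e^(−2Ns))), exact limit equivalences, and the qualitative
ordering of fitness-variance collapse across ruggedness 0/1/10 (L = 15,
N = 5000, 10 landscapes per level, 500 generations). Problem sizes in the
test suite (e.g. 10⁵ one-generation loss trials, 2000 selection replicates,
10 replicates of the N = 10⁴ fixation-time envelope) were chosen so the
whole suite completes in a few minutes on one core while keeping Monte-Carlo
standard errors well below the effect sizes under test.

Passing these tests shows the engine's sampling distributions are correct
under the stated model; it does not validate biological realism beyond the
model's assumptions: no diploidy or dominance, no population structure, no
overlapping generations, no crossover interference, no dynamic
fitness ("seascape") environments, exactly two alleles per locus, and an
initial population in linkage equilibrium.

## Known limitations

* Full-table landscapes are memory-bound (L ≤ 25); there is no on-the-fly
  fitness evaluation for larger L.
* With high mutation supply and many loci, the number of segregating
  genotypes — and hence runtime — grows quickly; the engine is vectorized
  but not parallel.
* Fixation times at record interval n > 1 are right-censored to recorded
  generations unless exact tracking is enabled.
* The e^(−i) loss approximation ignores the (1−i/N)^N < e^(−i) finite-N
  correction, a relative error below 0.5% for N ≥ 100.
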