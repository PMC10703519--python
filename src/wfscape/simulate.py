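"""Full-configuration simulation runs.

Glue between :mod:`config` and the engine: builds the landscape, the
recombination map and the initial populations a :class:`RunConfig`
describes, then runs the requested replicates with deterministically derived
seeds.

Seed scheme (all streams are numpy PCG64 generators):

* landscape: ``landscape_seed`` if set, else derived from
  ``master_seed`` with stream key (0, 0);
* replicate k initialization: derived from ``init_seed`` (or
  ``master_seed``) with stream key (1, k);
* replicate k generations: derived from ``master_seed`` with stream key
  (2, k).

Replicate streams depend only on the replicate index, never on a shared
sequential stream, so outputs are independent of execution order.
"""

from __future__ import annotations

import numpy as np

from .config import RunConfig
from .engine import (
    EngineConfig,
    RecombinationMap,
    replicate_seed_sequence,
    run_replicate,
)
from .landscapes import (
    FitnessLandscape,
    gen_additive,
    gen_block,
    gen_hoc,
    gen_nk,
    gen_rmf,
    read_landscape_csv,
)
from .population import Population, init_equal, init_sfs


def build_landscape(config: RunConfig) -> FitnessLandscape:
    """Generate (or read, for ``model = 'custom'``) the configured landscape."""
    if config.model == "custom":
        return read_landscape_csv(config.custom_landscape_path)
    if config.landscape_seed is not None:
        rng = np.random.default_rng(config.landscape_seed)
    else:
        rng = np.random.default_rng(replicate_seed_sequence(config.master_seed, 0, stream=0))
    kwargs = dict(effect=config.additive_effect, effect_sd=config.additive_sd, rng=rng)
    if config.model == "additive":
        return gen_additive(config.loci, **kwargs)
    if config.model == "rmf":
        sigma = 0.01 if config.sigma_epi is None else config.sigma_epi
        return gen_rmf(config.loci, sigma, **kwargs)
    if config.model == "nk":
        return gen_nk(config.loci, config.nk_k, scheme=config.nk_scheme, rng=rng)
    if config.model == "block":
        return gen_block(config.loci, config.blocks, rng=rng)
    return gen_hoc(config.loci, rng=rng)


def build_recombination_map(config: RunConfig) -> RecombinationMap:
    if config.recombination_mode == "custom":
        return RecombinationMap.from_file(config.recombination_map_path, L=config.loci)
    return RecombinationMap.uniform(config.loci, config.recombination_rate)


def build_initial_population(config: RunConfig, replicate: int = 0) -> Population:
    """Initial population for one replicate (its own derived seed stream)."""
    entropy = config.master_seed if config.init_seed is None else config.init_seed
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(entropy), spawn_key=(1, int(replicate)))
    )
    if config.init_mode == "equal":
        return init_equal(config.population_size, config.loci, config.equal_frequency, rng)
    return init_sfs(config.population_size, config.loci, config.drift_threshold, rng)


def engine_config(config: RunConfig) -> EngineConfig:
    return EngineConfig(
        mutation_rate=config.mutation_rate,
        max_generations=config.max_generations,
        record_interval=config.record_interval,
        exact_fixation_times=config.exact_fixation_times,
    )


def run_simulation(
    config: RunConfig, landscape: "FitnessLandscape | None" = None
) -> tuple:
    """Run all configured replicates.

    Returns ``(landscape, [ReplicateResult, ...])``.  Identical configs and
    seeds give bit-identical results.
    """
    if landscape is None:
        landscape = build_landscape(config)
    rmap = build_recombination_map(config)
    ecfg = engine_config(config)
    results = []
    for k in range(config.replicates):
        pop0 = build_initial_population(config, k)
        rng = np.random.default_rng(replicate_seed_sequence(config.master_seed, k, stream=2))
        results.append(
            run_replicate(
                pop0, landscape, rmap, ecfg, rng,
                dump_generations=config.dump_generations, replicate=k,
            )
        )
    return landscape, results
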