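"""Tabular output files.

All tabular outputs are TSV with a ``#``-prefixed metadata header block
(config echo, seeds, software version) so any file can be traced back to a
bit-identical re-run.  Population dumps aggregate individuals into
``(genotype bitstring, count)`` rows — individuals are exchangeable, so
counts are lossless and compact.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import ALL_STATS, RunConfig
from .engine import ReplicateResult
from .errors import ConfigError
from .landscapes import from_bitstring, to_bitstring, write_landscape_csv
from .population import Population
from .simulate import run_simulation
from .stats import RunSummary, UNFIXED


def _meta_block(meta: "dict | None") -> str:
    if not meta:
        return ""
    return "".join(f"# {key} = {value}\n" for key, value in meta.items())


def _base_meta(extra: "dict | None" = None) -> dict:
    meta = {"wfscape_version": __version__, "rng": "numpy PCG64"}
    if extra:
        meta.update(extra)
    return meta


def config_meta(config: RunConfig) -> dict:
    """Config echo for output headers (None fields omitted)."""
    meta = _base_meta()
    for f in dataclasses.fields(RunConfig):
        value = getattr(config, f.name)
        if value is not None:
            meta[f"config.{f.name}"] = value
    return meta


def _trajectory_frame(records, stats) -> pd.DataFrame:
    unknown = set(stats) - set(ALL_STATS)
    if unknown:
        raise ConfigError(f"unknown statistic(s) {sorted(unknown)}")
    columns = {"generation": [r.generation for r in records]}
    for stat in stats:
        if stat == "allele_freqs":
            freqs = np.vstack([r.allele_frequencies for r in records])
            for b in range(freqs.shape[1]):
                columns[f"freq_{b}"] = freqs[:, b]
        elif stat == "distance_to_peak":
            columns["distance_to_peak"] = [r.distance_to_peak for r in records]
            columns["distance_to_peak_best"] = [r.distance_to_peak_best for r in records]
        else:
            columns[stat] = [getattr(r, stat) for r in records]
    return pd.DataFrame(columns)


def write_trajectory(records, path, meta: "dict | None" = None, stats=ALL_STATS) -> None:
    """Write per-generation statistics as TSV (one row per recorded
    generation; columns chosen by ``stats``)."""
    if not records:
        raise ValueError("no trajectory records to write")
    frame = _trajectory_frame(records, stats)
    with open(path, "w") as fh:
        fh.write(_meta_block(_base_meta(meta)))
        frame.to_csv(fh, sep="\t", index=False)


def read_trajectory(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _summary_frame(summary: RunSummary, L: int, replicate: "int | None" = None) -> pd.DataFrame:
    fix = summary.fixation
    frame = pd.DataFrame(
        {
            "locus": np.arange(L),
            "fixation_time": fix.times,
            "fixed_allele": fix.alleles,
            "repolymorphized": fix.repolymorphized,
        }
    )
    if replicate is not None:
        frame.insert(0, "replicate", replicate)
    return frame


def _summary_meta(summary: RunSummary, L: int) -> dict:
    haplos = ";".join(f"{to_bitstring(g, L)}:{c}" for g, c in summary.final_haplotypes)
    return {
        "total_generations": summary.total_generations,
        "final_mean_fitness": repr(summary.final_mean_fitness),
        "reached_global_peak": summary.reached_global_peak,
        "final_haplotypes": haplos,
        "unfixed_marker": UNFIXED,
    }


def write_summary(summary: RunSummary, L: int, path, meta: "dict | None" = None) -> None:
    """Write an end-of-run summary: run-level fields as metadata lines, one
    table row per locus (fixation time, fixed allele, re-entry flag)."""
    header = _base_meta(meta)
    header.update(_summary_meta(summary, L))
    with open(path, "w") as fh:
        fh.write(_meta_block(header))
        _summary_frame(summary, L).to_csv(fh, sep="\t", index=False)


def write_combined_summary(results, L: int, path, meta: "dict | None" = None) -> None:
    """One summary table across replicates (rows = replicate x locus), with
    per-replicate run-level fields as metadata lines."""
    header = _base_meta(meta)
    for res in results:
        for key, value in _summary_meta(res.summary, L).items():
            if key != "unfixed_marker":
                header[f"rep{res.replicate}.{key}"] = value
    header["unfixed_marker"] = UNFIXED
    frames = [_summary_frame(res.summary, L, res.replicate) for res in results]
    with open(path, "w") as fh:
        fh.write(_meta_block(header))
        pd.concat(frames, ignore_index=True).to_csv(fh, sep="\t", index=False)


def dump_population(pop: Population, generation: int, path, meta: "dict | None" = None) -> None:
    """Write a population snapshot as aggregated ``genotype<TAB>count`` rows
    in ascending genotype-index order."""
    genotypes, counts = np.unique(pop.genotypes, return_counts=True)
    header = _base_meta(meta)
    header.update({"generation": int(generation), "loci": pop.L, "population_size": pop.N})
    with open(path, "w") as fh:
        fh.write(_meta_block(header))
        pd.DataFrame(
            {"genotype": [to_bitstring(g, pop.L) for g in genotypes], "count": counts}
        ).to_csv(fh, sep="\t", index=False)


def load_population_dump(path) -> tuple:
    """Read a population dump back as ``(Population, generation)``; the
    reconstructed multiset of genotypes is identical to the dumped one."""
    generation = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# generation ="):
                generation = int(line.split("=", 1)[1])
    frame = pd.read_csv(path, sep="\t", comment="#", dtype={"genotype": str})
    L = len(frame["genotype"].iloc[0])
    genotypes = np.repeat(
        [from_bitstring(b) for b in frame["genotype"]], frame["count"].to_numpy()
    ).astype(np.int64)
    return Population(L, genotypes), generation


def run_and_write(config: RunConfig, progress=None) -> list:
    """Run all replicates of a configuration and write every output file.

    Produces ``{prefix}_landscape.csv``, per-replicate
    ``{prefix}_rep{k}_trajectory.tsv`` / ``{prefix}_rep{k}_summary.tsv``,
    population dumps ``{prefix}_rep{k}_gen{g}_population.tsv`` for each
    requested dump generation, and a combined ``{prefix}_summary.tsv``.
    Returns the list of written paths.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    prefix = config.output_prefix
    meta = config_meta(config)
    written = []

    landscape, results = run_simulation(config)
    landscape_path = outdir / f"{prefix}_landscape.csv"
    write_landscape_csv(landscape, landscape_path)
    written.append(landscape_path)

    for res in results:
        rep_meta = dict(meta, replicate=res.replicate)
        traj_path = outdir / f"{prefix}_rep{res.replicate}_trajectory.tsv"
        write_trajectory(res.records, traj_path, rep_meta, stats=config.stats)
        written.append(traj_path)
        summ_path = outdir / f"{prefix}_rep{res.replicate}_summary.tsv"
        write_summary(res.summary, config.loci, summ_path, rep_meta)
        written.append(summ_path)
        for gen, pop in sorted(res.dumps.items()):
            dump_path = outdir / f"{prefix}_rep{res.replicate}_gen{gen}_population.tsv"
            dump_population(pop, gen, dump_path, rep_meta)
            written.append(dump_path)
        if progress is not None:
            progress(res)

    combined_path = outdir / f"{prefix}_summary.tsv"
    write_combined_summary(results, config.loci, combined_path, meta)
    written.append(combined_path)
    return written
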