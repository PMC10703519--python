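"""Run configuration: a flat key-value (TOML-syntax) file.

Every key is optional except ``model``, ``loci`` (inferable for custom
landscapes), ``population_size`` and ``master_seed``.  Defaults applied
during loading are logged on the ``wfscape`` logger.  Paths are resolved
relative to the directory containing the config file.

Keys
----
Landscape: ``model`` (additive | rmf | nk | block | hoc | custom), ``loci``,
``additive_effect`` or ``additive_sd`` (mutually exclusive), ``sigma_epi``,
``nk_k``, ``nk_scheme`` (adjacent | random), ``blocks``, ``landscape_seed``,
``custom_landscape_path``.

Initialization: ``init_mode`` (equal | sfs), ``equal_frequency``,
``drift_threshold``, ``init_seed``, ``population_size``.

Engine: ``recombination_mode`` (uniform | custom), ``recombination_rate``,
``recombination_map_path``, ``mutation_rate``, ``max_generations``,
``record_interval``, ``exact_fixation_times``.

Output / orchestration: ``replicates``, ``master_seed``, ``output_dir``,
``output_prefix``, ``dump_generations``, ``stats``.
"""

from __future__ import annotations

import dataclasses
import logging
import tomllib
from dataclasses import dataclass
from pathlib import Path

from .errors import ConfigError
from .landscapes import MAX_LOCI

logger = logging.getLogger("wfscape")

MODELS = ("additive", "rmf", "nk", "block", "hoc", "custom")
INIT_MODES = ("equal", "sfs")
RECOMBINATION_MODES = ("uniform", "custom")
NK_SCHEMES = ("adjacent", "random")

#: Selectable per-generation statistics (trajectory columns).
ALL_STATS = (
    "mean_fitness",
    "fitness_variance",
    "haplotype_diversity",
    "n_haplotypes",
    "distance_to_peak",
    "allele_freqs",
)


@dataclass(frozen=True)
class RunConfig:
    """Validated full simulation configuration (see module docstring)."""

    model: str
    loci: int
    population_size: int
    master_seed: int
    additive_effect: "float | None" = None
    additive_sd: "float | None" = None
    sigma_epi: "float | None" = None
    nk_k: "int | None" = None
    nk_scheme: str = "adjacent"
    blocks: "int | None" = None
    landscape_seed: "int | None" = None
    custom_landscape_path: "str | None" = None
    init_mode: str = "equal"
    equal_frequency: float = 0.5
    drift_threshold: int = 3
    init_seed: "int | None" = None
    recombination_mode: str = "uniform"
    recombination_rate: float = 0.0
    recombination_map_path: "str | None" = None
    mutation_rate: float = 0.0
    max_generations: "int | None" = None
    record_interval: int = 1
    exact_fixation_times: bool = False
    replicates: int = 1
    output_dir: str = "."
    output_prefix: str = "run"
    dump_generations: tuple = ()
    stats: tuple = ALL_STATS

    def __post_init__(self) -> None:
        def fail(msg):
            raise ConfigError(msg)

        if self.model not in MODELS:
            fail(f"model: must be one of {MODELS}, got {self.model!r}")
        if not (1 <= self.loci <= MAX_LOCI):
            fail(f"loci: must be in [1, {MAX_LOCI}], got {self.loci!r}")
        if self.population_size < 2 or self.population_size % 2:
            fail(f"population_size: must be even and >= 2, got {self.population_size!r}")
        if self.additive_effect is not None and self.additive_sd is not None:
            fail("additive_effect / additive_sd: mutually exclusive")
        if self.sigma_epi is not None and self.sigma_epi < 0:
            fail(f"sigma_epi: must be >= 0, got {self.sigma_epi}")
        if self.model == "nk":
            if self.nk_k is None:
                fail("nk_k: required for model = 'nk'")
            if not (0 <= self.nk_k <= self.loci - 1):
                fail(f"nk_k: must be in [0, loci-1 = {self.loci - 1}], got {self.nk_k}")
        if self.nk_scheme not in NK_SCHEMES:
            fail(f"nk_scheme: must be one of {NK_SCHEMES}, got {self.nk_scheme!r}")
        if self.model == "block":
            if self.blocks is None:
                fail("blocks: required for model = 'block'")
            if not (1 <= self.blocks <= self.loci):
                fail(f"blocks: must be in [1, loci = {self.loci}], got {self.blocks}")
        if self.model == "custom" and self.custom_landscape_path is None:
            fail("custom_landscape_path: required for model = 'custom'")
        if self.init_mode not in INIT_MODES:
            fail(f"init_mode: must be one of {INIT_MODES}, got {self.init_mode!r}")
        if not (0.0 < self.equal_frequency < 1.0):
            fail(f"equal_frequency: must be in (0, 1), got {self.equal_frequency}")
        if self.init_mode == "sfs" and not (1 <= self.drift_threshold <= self.population_size // 2):
            fail(
                "drift_threshold: must be in [1, population_size/2 = "
                f"{self.population_size // 2}], got {self.drift_threshold}"
            )
        if self.recombination_mode not in RECOMBINATION_MODES:
            fail(
                f"recombination_mode: must be one of {RECOMBINATION_MODES}, "
                f"got {self.recombination_mode!r}"
            )
        if self.recombination_mode == "uniform" and not (0.0 <= self.recombination_rate <= 0.5):
            fail(f"recombination_rate: must be in [0, 0.5], got {self.recombination_rate}")
        if self.recombination_mode == "custom" and self.recombination_map_path is None:
            fail("recombination_map_path: required for recombination_mode = 'custom'")
        if not (0.0 <= self.mutation_rate < 1.0):
            fail(f"mutation_rate: must be in [0, 1), got {self.mutation_rate}")
        if self.mutation_rate > 0 and self.max_generations is None:
            fail("max_generations: required when mutation_rate > 0")
        if self.max_generations is not None and self.max_generations < 1:
            fail(f"max_generations: must be >= 1, got {self.max_generations}")
        if self.record_interval < 1:
            fail(f"record_interval: must be >= 1, got {self.record_interval}")
        if self.replicates < 1:
            fail(f"replicates: must be >= 1, got {self.replicates}")
        object.__setattr__(self, "dump_generations", tuple(int(g) for g in self.dump_generations))
        if any(g < 0 for g in self.dump_generations):
            fail("dump_generations: entries must be >= 0")
        object.__setattr__(self, "stats", tuple(self.stats))
        unknown_stats = set(self.stats) - set(ALL_STATS)
        if unknown_stats:
            fail(f"stats: unknown statistic(s) {sorted(unknown_stats)}; choose from {ALL_STATS}")


_FIELDS = {f.name: f for f in dataclasses.fields(RunConfig)}
_INT_KEYS = {
    "loci", "population_size", "master_seed", "nk_k", "blocks", "landscape_seed",
    "drift_threshold", "init_seed", "max_generations", "record_interval", "replicates",
}
_FLOAT_KEYS = {
    "additive_effect", "additive_sd", "sigma_epi", "equal_frequency",
    "recombination_rate", "mutation_rate",
}
_STR_KEYS = {
    "model", "nk_scheme", "custom_landscape_path", "init_mode", "recombination_mode",
    "recombination_map_path", "output_dir", "output_prefix",
}
_BOOL_KEYS = {"exact_fixation_times"}
_LIST_KEYS = {"dump_generations", "stats"}
_PATH_KEYS = {"custom_landscape_path", "recombination_map_path", "output_dir"}


def _coerce(key: str, value):
    if key in _BOOL_KEYS:
        if not isinstance(value, bool):
            raise ConfigError(f"{key}: expected a boolean, got {value!r}")
        return value
    if key in _INT_KEYS:
        if isinstance(value, bool) or not isinstance(value, int):
            raise ConfigError(f"{key}: expected an integer, got {value!r}")
        return int(value)
    if key in _FLOAT_KEYS:
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ConfigError(f"{key}: expected a number, got {value!r}")
        return float(value)
    if key in _STR_KEYS:
        if not isinstance(value, str):
            raise ConfigError(f"{key}: expected a string, got {value!r}")
        return value
    if key in _LIST_KEYS:
        if not isinstance(value, (list, tuple)):
            raise ConfigError(f"{key}: expected a list, got {value!r}")
        return tuple(value)
    raise ConfigError(f"unknown configuration key {key!r}")


def _infer_loci_from_landscape(path: Path) -> int:
    """Peek the first data row of a landscape CSV for its bitstring length."""
    try:
        with open(path) as fh:
            next(fh)  # header
            first = next(fh)
    except (OSError, StopIteration) as exc:
        raise ConfigError(f"custom_landscape_path: cannot read {path}: {exc}") from exc
    return len(first.split(",")[0].strip())


def load_config(path) -> RunConfig:
    """Parse and validate a run configuration file.

    Unknown keys, type mismatches, and inconsistencies raise
    :class:`~wfscape.errors.ConfigError` naming the offending key.  Defaults
    applied for absent keys are logged.  Relative paths are resolved against
    the config file's directory.
    """
    path = Path(path)
    try:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    except OSError as exc:
        raise ConfigError(f"cannot read config file {path}: {exc}") from exc
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"config file {path} is not valid TOML: {exc}") from exc

    base = path.parent
    kwargs = {}
    for key, value in data.items():
        if key not in _FIELDS:
            raise ConfigError(f"unknown configuration key {key!r} in {path}")
        value = _coerce(key, value)
        if key in _PATH_KEYS:
            value = str((base / value).resolve()) if not Path(value).is_absolute() else value
        kwargs[key] = value

    # the default output directory is the config file's own directory
    kwargs.setdefault("output_dir", str(base.resolve()))

    for key in ("model", "population_size", "master_seed"):
        if key not in kwargs:
            raise ConfigError(f"missing required configuration key {key!r}")
    if "loci" not in kwargs:
        if kwargs["model"] == "custom":
            kwargs["loci"] = _infer_loci_from_landscape(Path(kwargs["custom_landscape_path"]))
            logger.info("loci inferred from custom landscape: %d", kwargs["loci"])
        else:
            raise ConfigError("missing required configuration key 'loci'")

    config = RunConfig(**kwargs)

    for name, f in _FIELDS.items():
        if name not in kwargs:
            logger.info("config default applied: %s = %r", name, getattr(config, name))

    if config.recombination_mode == "custom":
        try:
            with open(config.recombination_map_path) as fh:
                n_lines = sum(1 for line in fh if line.strip() and not line.startswith("#"))
        except OSError as exc:
            raise ConfigError(
                f"recombination_map_path: cannot read {config.recombination_map_path}: {exc}"
            ) from exc
        if n_lines != config.loci - 1:
            raise ConfigError(
                f"recombination_map_path: map has {n_lines} rates, "
                f"expected L-1 = {config.loci - 1}"
            )
    return config


def _toml_value(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    if isinstance(value, str):
        escaped = value.replace("\\", "\\\\").replace('"', '\\"')
        return f'"{escaped}"'
    if isinstance(value, (list, tuple)):
        return "[" + ", ".join(_toml_value(v) for v in value) + "]"
    raise TypeError(f"cannot serialize {value!r}")


def config_to_toml(config: RunConfig) -> str:
    """Render a config as flat TOML (``None`` fields omitted)."""
    lines = []
    for f in dataclasses.fields(RunConfig):
        value = getattr(config, f.name)
        if value is None:
            continue
        lines.append(f"{f.name} = {_toml_value(value)}")
    return "\n".join(lines) + "\n"


def write_config(config: RunConfig, path) -> None:
    """Write a config file that :func:`load_config` parses back to an equal
    :class:`RunConfig`."""
    Path(path).write_text(config_to_toml(config))
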