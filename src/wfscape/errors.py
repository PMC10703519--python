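"""Exception hierarchy.

Everything raised deliberately by wfscape derives from :class:`WfscapeError`,
so callers (and the CLI) can distinguish usage problems from genuine bugs.
"""


class WfscapeError(Exception):
    """Base class for all wfscape errors."""


class InvalidParameterError(WfscapeError, ValueError):
    """A parameter is outside its documented domain."""


class LandscapeFormatError(WfscapeError, ValueError):
    """A fitness-landscape table is malformed (missing/duplicate genotypes,
    inconsistent bitstring lengths, bad values)."""


class ConfigError(WfscapeError, ValueError):
    """A run configuration is unreadable, has unknown keys, or is internally
    inconsistent."""


class DegeneratePopulationError(WfscapeError, RuntimeError):
    """Selection cannot proceed: every gamete in the pool has fitness zero."""
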