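"""Exception hierarchy shared across the package.

The CLI maps these onto process exit codes: configuration problems (2),
data validation problems (3), statistical degeneracy (4).
"""


class TcradError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(TcradError):
    """Invalid configuration (bad proportions, negative variances, ...)."""


class SchemaError(TcradError):
    """A table is missing mandatory columns or uses an unknown dialect."""


class DataValidationError(TcradError):
    """A table violates a content invariant (negative intake, duplicates)."""


class CompletenessError(DataValidationError):
    """A required (component, sex) cell or stratum is absent."""


class ScoringError(TcradError):
    """A participant cannot be scored (missing component intake)."""


class DegenerateDataError(TcradError):
    """A statistical operation received degenerate input (constant energy,
    single-level factor, too few observations)."""
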