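"""Exception hierarchy shared across the package.

Errors are grouped so callers (and the CLI exit-code mapping) can
distinguish configuration problems, malformed input data, and
degenerate runtime conditions.
"""


class TrapquantError(Exception):
    """Base class for all package errors."""


class ConfigError(TrapquantError):
    """Invalid configuration value or combination."""


class SchemaError(TrapquantError):
    """An input table does not have the expected columns/dialect."""


class MalformedChannelError(TrapquantError):
    """A precursor id carries both heavy and light SILAC tags."""


class UnlabeledPrecursorError(TrapquantError):
    """A precursor id carries no SILAC channel tag."""


class DuplicateCellError(TrapquantError):
    """Two records map to the same (feature, sample) matrix cell."""


class UnknownRunError(TrapquantError):
    """A record references a run_id absent from the sample design."""


class DesignError(TrapquantError):
    """The sample design violates an invariant or lacks required samples."""


class DegenerateSampleError(TrapquantError):
    """A sample column has no usable (non-missing) values."""


class InsufficientOverlapError(TrapquantError):
    """Too few shared features between two samples for pairwise fitting."""


class InsufficientDataError(TrapquantError):
    """Not enough values to compute the requested statistic."""


class MethodUnavailableError(TrapquantError):
    """The requested method cannot run on this input shape."""


class ComparisonError(TrapquantError):
    """Two pipeline runs are not comparable (mismatched designs)."""
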