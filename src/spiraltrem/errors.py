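"""Exception hierarchy shared across the package."""


class SpiraltremError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SpiraltremError, ValueError):
    """A simulation or run configuration violates its invariants.

    The message names the offending field.
    """


class SvcParseError(SpiraltremError, ValueError):
    """A pen-recording file could not be parsed; message carries the line number."""


class ValidationError(SpiraltremError, ValueError):
    """An in-memory object violates a structural invariant."""


class DegenerateInputError(SpiraltremError, ValueError):
    """A variable is constant (zero variance) on the complete cases."""


class SampleSizeError(SpiraltremError, ValueError):
    """Too few complete cases for the requested statistic (df would be < 1)."""


class AnalysisError(SpiraltremError, RuntimeError):
    """A pipeline stage failed; message names the stage."""
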