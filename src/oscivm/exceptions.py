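"""Exception hierarchy shared across modules."""


class OscivmError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OscivmError, ValueError):
    """Invalid generator or pipeline configuration."""


class InputError(OscivmError, ValueError):
    """Malformed or degenerate input data."""


class SingularFitError(OscivmError, ValueError):
    """Rank-deficient design; the message names the offending columns/frequency."""


class NormalizationError(OscivmError, ValueError):
    """Percent-signal-change normalization is undefined (zero-mean series)."""


class PipelineError(OscivmError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
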