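"""Exception hierarchy for the pipeline.

Everything derives from :class:`NptNetError` so callers can catch pipeline
failures with a single ``except`` clause; each subclass marks a distinct
failure contract (degenerate input, schema mismatch, stage ordering, ...).
"""


class NptNetError(ValueError):
    """Base class for all package-specific errors."""


class ConfigurationError(NptNetError):
    """A configuration value violates its documented invariant."""


class DegenerateSignalError(NptNetError):
    """An epoch has zero variance (constant signal) where variance is required."""


class DegenerateBandError(NptNetError):
    """A spectral band contains no power, so a band statistic is undefined."""


class DegenerateVariableError(NptNetError):
    """A variable is constant, so a rank correlation is undefined."""


class DomainError(NptNetError):
    """A frequency band or value lies outside the supported domain."""


class InputError(NptNetError):
    """An input sequence is too short or otherwise malformed."""


class ExtractionError(NptNetError):
    """Feature extraction failed for a subject/ROI (e.g. all epochs degenerate)."""


class AssemblyError(NptNetError):
    """A parameter table could not be assembled (missing subject/session)."""


class MappingError(NptNetError):
    """An external table could not be mapped onto the canonical schema."""


class PairingError(NptNetError):
    """Two bootstrap ensembles cannot be paired (mismatched nodes/resamples)."""


class StageDependencyError(NptNetError):
    """A pipeline stage was requested before its prerequisite stage."""


class UndefinedTestError(NptNetError):
    """A statistical test is undefined for the given data (e.g. all-zero diffs)."""
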