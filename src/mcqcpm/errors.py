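"""Exception hierarchy shared across the package."""


class McqCpmError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(McqCpmError):
    """A configuration object violates one of its invariants."""


class SubjectExcludedError(McqCpmError):
    """A subject cannot be analyzed (e.g. too few frames after scrubbing)."""


class DegenerateDataError(McqCpmError):
    """Input data are degenerate: constant series, zero variance, collinearity."""


class EmptyMaskError(McqCpmError):
    """An edge mask is empty where a nonempty mask is required."""


class StageError(McqCpmError):
    """A pipeline stage failed; the message names the stage."""
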