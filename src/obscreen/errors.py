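"""Exception hierarchy.

Everything raised deliberately by the package derives from
:class:`ObscreenError`, so callers (and the CLI) can distinguish
validation failures from genuine bugs.
"""


class ObscreenError(Exception):
    """Base class for all package errors."""


class SchemaError(ObscreenError):
    """Unknown item, period, or malformed questionnaire schema."""


class CodingError(ObscreenError):
    """A raw answer matches neither the positive nor the negative set."""


class CohortParseError(ObscreenError):
    """A cohort CSV could not be parsed into typed records."""


class ParameterError(ObscreenError):
    """Invalid simulation or analysis parameters."""


class CollinearityError(ObscreenError):
    """Rank-deficient design matrix; carries the aliased item ids."""

    def __init__(self, aliased, message=None):
        self.aliased = list(aliased)
        super().__init__(message or f"rank-deficient design; aliased items: {self.aliased}")


class DegenerateInputError(ObscreenError):
    """Zero-variance or one-class input where a statistic is undefined."""


class PipelineOrderError(ObscreenError):
    """A derivation stage received input that an earlier stage should have removed."""


class ToolValidationError(ObscreenError):
    """A screening-tool definition violates its invariants."""
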