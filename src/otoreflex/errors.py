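"""Exception hierarchy.

Validation problems (bad config, malformed files, infeasible protocol
parameters) derive from :class:`ValidationError`; everything else that the
pipeline can raise derives from :class:`OtoreflexError`.  The CLI maps
ValidationError to exit code 2 and other package errors to exit code 3.
"""


class OtoreflexError(Exception):
    """Base class for all package errors."""


class ValidationError(OtoreflexError, ValueError):
    """Invalid configuration or input that is rejected before computation."""


class ParameterizationError(ValidationError):
    """A protocol parameter set admits no valid stimulus profile."""


class FormatError(ValidationError):
    """A file does not conform to the expected tabular format."""


class ProtocolMismatchError(OtoreflexError):
    """Recorded series and stimulus description do not match."""


class OutOfModelError(OtoreflexError):
    """A landmark or pose falls outside the spherical-eye projection model."""


class TorsionUnobservableError(OutOfModelError):
    """Freckle coincides with the pupil centre; torsion cannot be solved."""


class FitError(OtoreflexError):
    """A stimulus-response table is too degenerate to fit."""


class PipelineError(OtoreflexError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
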