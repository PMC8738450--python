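"""Exception hierarchy for the reduction-assessment pipeline."""


class OsteoreduceError(Exception):
    """Base class for all package errors."""


class GenerationError(OsteoreduceError):
    """Synthetic anatomy could not be built as a closed manifold."""


class CutError(OsteoreduceError):
    """A fracture plane missed the bone or produced an invalid split."""


class FitError(OsteoreduceError):
    """Degenerate input to a geometric least-squares fit."""


class DetectionError(OsteoreduceError):
    """The mesh does not look like a long bone; landmarks cannot be found."""


class RegistrationError(OsteoreduceError):
    """The anchor landmarks are degenerate (e.g. collinear)."""


class SessionError(OsteoreduceError):
    """A session event log violates its ordering or completeness rules."""


class FormatError(OsteoreduceError):
    """A file could not be read or written in the expected format."""

    def __init__(self, path, reason):
        super().__init__(f"{path}: {reason}")
        self.path = str(path)
        self.reason = reason
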