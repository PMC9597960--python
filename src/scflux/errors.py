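"""Exception hierarchy shared across the package."""


class ScfluxError(Exception):
    """Base class for all scflux errors."""


class ValidationError(ScfluxError):
    """A domain object violates one of its structural invariants."""


class ModelParseError(ScfluxError):
    """A model file could not be parsed; the message names the offending element."""


class GPRParseError(ScfluxError):
    """A gene-protein-reaction rule string is malformed.

    Carries the 0-based character ``position`` of the offending token.
    """

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


class ConfigurationError(ScfluxError):
    """An unknown preset, stage or option was requested."""


class ReadError(ScfluxError):
    """An expression-matrix file set is inconsistent or unreadable."""


class EmptyResultError(ScfluxError):
    """A filter removed every cell (or reaction), leaving nothing to analyse."""


class InfeasibleModelError(ScfluxError):
    """The base LP {S·v = 0, v_L ≤ v ≤ v_U} admits no solution."""


class DenoiserUnavailableError(ScfluxError):
    """An external denoising tool is not installed; the message carries an install hint."""
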