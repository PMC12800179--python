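"""Exception hierarchy for affetds.

All errors raised by the package derive from :class:`AffetdsError` so callers
can catch the package's failures with a single except clause. Subclasses keep
the distinction the pipeline stages care about (bad parameters vs. geometry vs.
numerics vs. configuration).
"""


class AffetdsError(Exception):
    """Base class for all affetds errors."""


class ParameterError(AffetdsError, ValueError):
    """An argument violates its documented domain (e.g. negative epsilon)."""


class PlacementError(AffetdsError, ValueError):
    """A tumor does not fit inside the head region of the phantom."""


class NoSurroundingTissueError(AffetdsError, ValueError):
    """A removal mask leaves no boundary ring to estimate fill statistics from."""


class ShapeError(AffetdsError, ValueError):
    """An array has the wrong shape or length for the operation."""


class NumericalError(AffetdsError, ArithmeticError):
    """A non-finite value appeared where the algorithm requires finite numbers."""


class NotFittedError(AffetdsError, RuntimeError):
    """Prediction was requested from a model that has not been trained."""


class ConfigError(AffetdsError, ValueError):
    """A configuration file contains unknown keys or invalid values.

    The message lists every offending key at once.
    """


class StageError(AffetdsError, RuntimeError):
    """A pipeline stage failed; the stage name is attached to the message."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
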