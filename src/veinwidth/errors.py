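"""Exception hierarchy for the vein-width pipeline.

Every stage raises a subclass of :class:`VeinWidthError` so callers (and the
CLI) can distinguish bad inputs from numerical failures without string
matching.
"""


class VeinWidthError(Exception):
    """Base class for all errors raised by this package."""


class InputError(VeinWidthError):
    """An input file is missing, unreadable, or not a supported raster."""


class ValidationError(VeinWidthError):
    """An argument violates a documented precondition."""


class ConfigurationError(VeinWidthError):
    """The pipeline configuration is inconsistent or incomplete."""


class NumericalError(VeinWidthError):
    """A numerical method produced non-finite values."""


class StageError(VeinWidthError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
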