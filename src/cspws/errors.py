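"""Typed exceptions used across the package."""


class CspwsError(Exception):
    """Base class for all package errors."""


class ValidationError(CspwsError, ValueError):
    """A parameter or input violates a documented contract."""


class SizingError(ValidationError):
    """A grid, frame or morphology is too small for the requested content."""


class CalibrationError(CspwsError):
    """The sigma(D) forward table could not be built or used."""


class CubeIOError(CspwsError):
    """A cube/mask file is missing metadata or cannot be parsed."""


class StageError(CspwsError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
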