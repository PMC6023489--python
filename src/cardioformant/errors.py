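"""Exception hierarchy shared across the package."""


class CardioformantError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CardioformantError):
    """Input file is not in an accepted format (e.g. multi-channel WAV)."""


class ParameterError(CardioformantError, ValueError):
    """A parameter is out of its valid range."""


class EmptyInputError(CardioformantError, ValueError):
    """Input is too short or empty for the requested operation."""


class DegenerateFrameError(CardioformantError):
    """A frame is all-zero or constant and cannot support an LPC fit."""


class MissingCellError(CardioformantError):
    """A required (site, formant) feature cell is absent from the cohort."""
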