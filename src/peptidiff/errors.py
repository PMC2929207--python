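"""Exception hierarchy shared across the package."""


class PeptidiffError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PeptidiffError):
    """An invalid configuration value; the message names the offending field."""


class CalibrationError(PeptidiffError):
    """Raised when too few reference peaks are matched to fit a calibration.

    Attributes
    ----------
    n_matched : int
        Number of reference masses that found a peak within tolerance.
    """

    def __init__(self, message: str, n_matched: int):
        super().__init__(message)
        self.n_matched = n_matched


class MatrixParseError(PeptidiffError):
    """Malformed analysis-matrix file; carries the offending location.

    ``row`` and ``column`` are human-oriented labels (header names or
    1-based file coordinates), not array indices.
    """

    def __init__(self, message: str, row=None, column=None):
        super().__init__(message)
        self.row = row
        self.column = column


class PipelineError(PeptidiffError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
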