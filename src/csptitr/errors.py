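"""Exception hierarchy shared across the package."""


class CsptitrError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(CsptitrError, ValueError):
    """A physical or configuration parameter violates its domain."""


class PeaklistParseError(CsptitrError, ValueError):
    """A peak-list row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class DuplicateLabelError(CsptitrError, ValueError):
    """Two peaks in one list share an assignment label."""


class ManifestError(CsptitrError, ValueError):
    """A titration-series manifest is incomplete or inconsistent."""


class DegenerateCalibrationError(CsptitrError, ValueError):
    """Endpoint intensities coincide; the TSP calibration line is undefined."""


class InsufficientDataError(CsptitrError, ValueError):
    """Too few points/steps/residues for the requested computation."""


class SingularCovarianceError(CsptitrError, RuntimeError):
    """Covariance matrix is singular; confidence intervals unavailable."""


class PDBFormatError(CsptitrError, ValueError):
    """A fixed-column PDB record is malformed; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class StageError(CsptitrError, RuntimeError):
    """A pipeline stage failed; message is prefixed with the stage name."""
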