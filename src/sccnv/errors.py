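"""Exception hierarchy used across the pipeline.

Exit-code mapping for the CLI: :class:`QcFailureError` maps to exit code 2,
input/configuration problems to exit code 3.
"""


class SccnvError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(SccnvError, ValueError):
    """A parameter violates its contract (e.g. non-positive window size)."""


class ConfigurationError(SccnvError):
    """Inputs are inconsistent with each other (missing chromosome, name mismatch)."""


class InsufficientDataError(SccnvError):
    """Too little usable data to carry out an operation."""


class GridMismatchError(SccnvError):
    """A count table or profile refers to a different window grid."""


class CalibrationError(SccnvError):
    """A simulator calibration target is unreachable (e.g. below the Poisson floor)."""


class QcFailureError(SccnvError):
    """Sample failed the quality gate (MAPD or coverage-uniformity rule)."""

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report
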