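"""Exception hierarchy.

Each error class carries the process exit code used by the command-line
interface (0 ok, 2 validation, 3 identification, 4 convergence).
"""


class MVMRError(Exception):
    """Base class for all package errors."""

    exit_code = 2


class ValidationError(MVMRError, ValueError):
    """Invalid argument, malformed input file, or inconsistent configuration."""

    exit_code = 2


class RankError(MVMRError, ValueError):
    """Rank-deficient design matrix; names the offending columns when known."""

    exit_code = 2

    def __init__(self, message, columns=None):
        super().__init__(message)
        self.columns = tuple(columns) if columns is not None else ()


class CovarianceValidityError(ValidationError):
    """Supplied variance/covariance terms imply a non-positive variance."""

    exit_code = 2


class IdentificationError(MVMRError, ValueError):
    """Model under- or exactly identified where over-identification is required."""

    exit_code = 3


class ConvergenceError(MVMRError, RuntimeError):
    """Iterative procedure failed to converge; carries the last iterate."""

    exit_code = 4

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate
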