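"""Exception hierarchy shared across the package.

Exit-code mapping used by the command line interface:
validation problems exit with status 2, convergence failures with status 3.
"""


class UoAError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(UoAError):
    """Raised when input data violate a structural invariant."""

    exit_code = 2


class ConvergenceError(UoAError):
    """Raised when an iterative fit fails to converge."""

    exit_code = 3
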