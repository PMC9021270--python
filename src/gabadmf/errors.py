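"""Exception hierarchy shared across the package.

Validation failures (bad user input, malformed matrices) are kept distinct
from numerical failures (integration blow-up, non-convergence) so the CLI
can map them to distinct exit codes.
"""


class GabadmfError(Exception):
    """Base class for all package errors."""


class ValidationError(GabadmfError):
    """Input fails a structural precondition (shape, sign, symmetry...)."""


class AlignmentError(ValidationError):
    """Objects that must share a region set / label order do not."""


class DegenerateInputError(ValidationError):
    """Input is structurally valid but degenerate (e.g. constant map)."""


class NumericalError(GabadmfError):
    """An integration or filtering step produced non-finite values."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class ConvergenceError(GabadmfError):
    """An iterative procedure exhausted its budget without converging."""
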