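"""Exception hierarchy.

Validation problems (bad user input) are kept distinct from numerical
failures (solver or fit did not converge) so callers — and the CLI exit
codes — can tell them apart.
"""


class FerrispecError(Exception):
    """Base class for all package errors."""


class ValidationError(FerrispecError, ValueError):
    """Input violates a precondition (negative pool, bad pH, ...)."""


class SolverError(FerrispecError, RuntimeError):
    """Equilibrium solver failed to converge; carries a residual report."""

    def __init__(self, message: str, residuals: dict | None = None):
        super().__init__(message)
        self.residuals = residuals or {}


class FitError(FerrispecError, RuntimeError):
    """Curve fit failed or the data are degenerate for the model."""


class ConfigError(FerrispecError, ValueError):
    """Malformed configuration file or unknown key."""
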