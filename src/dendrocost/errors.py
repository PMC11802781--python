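"""Exception hierarchy.

Exit-code mapping used by the CLI: configuration errors (2), data/schema
errors (3), numerical failures (4).
"""


class DendrocostError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DendrocostError):
    """Invalid parameter values or malformed configuration."""


class DataError(DendrocostError):
    """Malformed input tables, missing columns, empty joins."""


class NumericalError(DendrocostError):
    """Solver non-convergence or ill-conditioned fits; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
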