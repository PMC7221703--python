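"""Exception hierarchy shared across the package.

The CLI maps these onto process exit codes: configuration problems exit
with 2, data validation/parsing problems with 3, and random-walk
non-convergence with 4.
"""

from __future__ import annotations


class HerbnetError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(HerbnetError):
    """Invalid or incomplete pipeline configuration (exit code 2)."""


class ParseError(HerbnetError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(HerbnetError):
    """Well-formed input violating a model invariant (exit code 3)."""


class ParameterError(HerbnetError):
    """Infeasible or out-of-range generator/algorithm parameters."""


class ConvergenceError(HerbnetError):
    """Random walk failed to reach the residual threshold (exit code 4)."""

    def __init__(self, message: str, residual: float, iterations: int):
        self.residual = residual
        self.iterations = iterations
        super().__init__(f"{message} (residual={residual:.3e} after {iterations} iterations)")
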