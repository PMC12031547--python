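"""Exception hierarchy.

Validation problems (bad inputs, bad configuration) raise
:class:`ValidationError`; numerical failures raise
:class:`NonConvergenceError`.  The CLI maps the former to exit code 1 and
the latter to exit code 2.
"""

from __future__ import annotations


class UnderIceError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(UnderIceError, ValueError):
    """An input, configuration field, or file failed validation."""


class DegenerateDesignError(ValidationError):
    """A regression design matrix is singular (e.g. all times identical)."""


class CoverageError(ValidationError):
    """A prediction source does not cover every observed coordinate."""

    def __init__(self, message: str, missing=None):
        super().__init__(message)
        self.missing = list(missing) if missing is not None else []


class NonConvergenceError(UnderIceError, RuntimeError):
    """No optimizer start converged; carries best-effort diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class PipelineError(UnderIceError):
    """A pipeline stage failed; names the stage and offending unit."""

    def __init__(self, stage: str, detail: str, cause: Exception | None = None):
        super().__init__(f"pipeline stage '{stage}' failed: {detail}")
        self.stage = stage
        self.cause = cause
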