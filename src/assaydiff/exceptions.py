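"""Exception hierarchy shared across the pipeline stages."""


class AssayDiffError(Exception):
    """Base class for all package errors."""


class SchemaError(AssayDiffError):
    """The input table is missing a required column or has an unusable header."""


class ValidationError(AssayDiffError):
    """One or more rows (or a config) failed validation.

    Carries ``diagnostics``: a list of human-readable, row-indexed messages.
    """

    def __init__(self, message: str, diagnostics: list[str] | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        base = super().__str__()
        if self.diagnostics:
            return base + "\n  " + "\n  ".join(self.diagnostics)
        return base


class InsufficientDataError(AssayDiffError):
    """Fewer samples than the statistic requires."""


class DegenerateStatisticError(AssayDiffError):
    """A statistic is undefined for these inputs (zero variance, zero denominator...)."""


class SingularDesignError(AssayDiffError):
    """Regression design matrix is rank deficient (e.g. constant predictor)."""


class InfeasibleError(AssayDiffError):
    """A configuration cannot be satisfied (e.g. more clusters than points)."""
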