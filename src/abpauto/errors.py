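"""Exception hierarchy for the ABPM / autonomic-dysfunction pipeline."""


class ABPError(Exception):
    """Base class for all package errors."""


class FormatError(ABPError):
    """A file does not match its expected schema (missing column, bad header)."""


class RowError(ABPError):
    """A single data row failed to parse; carries the 1-based file line number."""

    def __init__(self, message: str, line_no: int):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


class ValidationError(ABPError):
    """A typed record violates a domain constraint (range, closed set)."""


class DegenerateTraceError(ABPError):
    """Too few plausible readings remain for any trace-level analysis."""


class JournalInconsistencyError(ABPError):
    """Journal sleep/wake events cannot define a night window."""


class UnevaluableError(ABPError):
    """A classifier cannot be evaluated for this subject (missing inputs)."""


class UndefinedStatisticError(ABPError):
    """A statistic is undefined for the given data (zero variance, empty class)."""


class SeparationError(ABPError):
    """Complete or quasi-complete separation in a logistic model."""


class ConvergenceError(ABPError):
    """Iterative fit failed to converge; carries the iteration trace if known."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


class SpecificationError(ABPError):
    """A simulation specification is internally infeasible."""
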