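"""Exception hierarchy for lenspue."""


class LenspueError(Exception):
    """Base class for all package errors."""


class DataValidationError(LenspueError):
    """A phenotype table violates a structural invariant (duplicates,
    missing columns, non-numeric or negative values, unknown codes)."""


class ConfigError(LenspueError):
    """A run or simulation configuration is invalid."""


class UnbalancedDesignError(LenspueError):
    """An operation requiring a balanced design received unequal replicate
    counts; balance or subsample the table first."""


class DomainError(LenspueError):
    """An arithmetic operation was called outside its mathematical domain
    (e.g. heritability with all variance components zero)."""
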