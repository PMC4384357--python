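"""Exception hierarchy."""


class BatchsurvError(Exception):
    """Base class for all package errors."""


class FormatError(BatchsurvError):
    """A cohort file does not have the expected columns/layout."""


class ValidationError(BatchsurvError):
    """Data violate a cohort invariant (negative time, split batch, ...)."""


class ConfigurationError(BatchsurvError):
    """An infeasible or inconsistent configuration was requested."""


class ConvergenceError(BatchsurvError):
    """An iterative fit failed to converge; carries diagnostics in args."""
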