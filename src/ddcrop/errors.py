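"""Exception hierarchy for ddcrop."""


class DdcropError(Exception):
    """Base class for all package errors."""


class InvalidInputError(DdcropError, ValueError):
    """An operation received arguments violating its preconditions."""


class InvalidConfigError(DdcropError, ValueError):
    """A configuration object is internally inconsistent."""


class MissingDataError(DdcropError):
    """Required data (weather days, benchmark candidates, ...) are absent."""


class InternalConsistencyError(DdcropError, RuntimeError):
    """A state invariant was violated during simulation (bookkeeping bug)."""


class ProjectionFailureError(DdcropError, RuntimeError):
    """Feasibility projection did not converge."""


class ImputationError(DdcropError):
    """Imputation is impossible (no non-missing donors anywhere)."""


class LoadError(DdcropError):
    """A tabular input failed schema or unit validation."""
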