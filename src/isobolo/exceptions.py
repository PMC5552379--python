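"""Exception hierarchy for dose-effect data validation and model fitting."""


class IsoboloError(Exception):
    """Base class for all package errors."""


class ValidationError(IsoboloError, ValueError):
    """Input data violates a structural or range invariant."""


class DegenerateDesignError(IsoboloError, ValueError):
    """The dose design cannot support the requested fit (e.g. a single dose level)."""


class InsufficientDataError(IsoboloError, ValueError):
    """Too few records for the requested analysis."""


class UndefinedDoseError(IsoboloError, ValueError):
    """An effective dose is undefined (zero slope)."""
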