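"""Exception hierarchy shared across the package."""


class NetSurvivalError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(NetSurvivalError):
    """A required column or field is missing or malformed."""


class RegistryMismatchError(NetSurvivalError):
    """Known-population columns do not match the registry."""


class ValidationError(NetSurvivalError):
    """A record violates a data invariant (e.g. nonpositive weight)."""


class DesignError(NetSurvivalError):
    """The sampling design cannot support the requested operation."""


class EstimationError(NetSurvivalError):
    """An estimator's preconditions are not met (e.g. empty group)."""


class ScheduleError(NetSurvivalError):
    """An age-band schedule is incomplete or inconsistent."""


class InstabilityError(NetSurvivalError):
    """Too many bootstrap replicates failed to produce a value."""


class GenerationError(NetSurvivalError):
    """A synthetic-data scenario is infeasible as configured."""
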