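"""Exception hierarchy shared across the package."""


class PatientCostError(Exception):
    """Base class for all package errors."""


class SchemaError(PatientCostError):
    """An input record is missing a required field or violates an invariant."""


class ReferentialError(PatientCostError):
    """A record references an id that does not resolve (e.g. unknown authority)."""


class ConfigurationError(PatientCostError):
    """A required parameter, rate or time profile is missing or inconsistent."""


class UnreachableError(PatientCostError):
    """No road-network path exists between a region centroid and any facility."""
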