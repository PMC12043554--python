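"""Exception hierarchy shared across the toolkit."""


class CSFToolkitError(Exception):
    """Base class for all toolkit errors."""


class SchemaError(CSFToolkitError):
    """A required column or field is missing or malformed."""


class CohortValidationError(CSFToolkitError):
    """A patient row violates a record invariant (names the patient)."""


class ConfigurationError(CSFToolkitError):
    """Inconsistent or unknown configuration (units, probabilities, factors)."""


class DomainError(CSFToolkitError):
    """An input is outside the mathematical domain of an operation."""
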