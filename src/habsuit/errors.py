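"""Exception hierarchy shared across the package."""


class HabsuitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HabsuitError):
    """A setting or argument is outside its documented domain."""


class DataError(HabsuitError):
    """Input data violate a precondition (empty, malformed, inconsistent)."""


class SchemaError(DataError):
    """A tabular input does not match the declared variable roster."""


class EvaluationError(HabsuitError):
    """A model could not be evaluated on a record."""
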