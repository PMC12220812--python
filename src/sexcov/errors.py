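"""Exception hierarchy for the sexcov pipeline."""


class SexcovError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(SexcovError):
    """A config file, column mapping, or parameter set is malformed."""


class ValidationError(SexcovError):
    """Input data violate a contract (duplicates, inclusion rules, shapes)."""


class GenerationError(SexcovError):
    """A synthetic-cohort configuration cannot produce valid data
    (e.g. an implied correlation matrix is not positive semi-definite)."""
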