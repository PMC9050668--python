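"""Exception hierarchy shared across the pipeline."""


class DogyearsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DogyearsError):
    """A config file, dialect mapping or search-term grammar problem."""


class DataError(DogyearsError):
    """Input data violates a contract (duplicate ids, negative counts, ...)."""


class EstimationError(DogyearsError):
    """An estimator could not produce a result (e.g. all bootstrap
    iterations rejected by the eligibility rule)."""
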