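"""Exception hierarchy for the validation pipeline."""


class CohortValError(Exception):
    """Base class for all package errors."""


class ConfigError(CohortValError):
    """A configuration field is missing or out of its admissible range."""


class InputError(CohortValError):
    """An input table violates a structural precondition (duplicate codes,
    mixed analytes, mismatched lengths, ...)."""


class DataError(CohortValError):
    """A record carries a physically impossible value (negative CD4 count,
    nonpositive detectable viral load, negative follow-up interval, ...)."""
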