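"""Exception hierarchy.

Exit-code mapping used by the CLI: configuration errors -> 2, data errors
-> 3, optimization failures -> 4.
"""


class PsoImputeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PsoImputeError):
    """Invalid configuration, option combination or schema declaration."""


class SchemaError(ConfigurationError):
    """Variable schema is inconsistent or does not match the data."""


class DataError(PsoImputeError):
    """The data violate a precondition (parse failure, degenerate input...)."""


class ParseError(DataError):
    """A cell could not be parsed under its declared variable type."""


class DegenerateInputError(DataError):
    """An operation would leave no usable data."""


class OptimizationFailureError(PsoImputeError):
    """The swarm search could not produce a usable assignment."""
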