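"""Exception hierarchy shared by all ricotem modules."""


class RicotemError(Exception):
    """Base class for all errors raised by this package."""


class InvalidInputError(RicotemError, ValueError):
    """A value or data structure violates a precondition (e.g. AUC_extem <= 0)."""


class InvalidTraceError(InvalidInputError):
    """A clot-amplitude trace is degenerate or malformed."""


class InvalidParameterError(RicotemError, ValueError):
    """A configuration or tuning parameter is out of its valid range."""


class InsufficientSpanError(RicotemError):
    """The trace does not cover the time span a computation requires (no extrapolation)."""


class MissingDataError(RicotemError):
    """A required measurement is absent for one or more identified patients."""


class SchemaError(RicotemError):
    """An input file does not conform to the expected CSV/YAML schema."""
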