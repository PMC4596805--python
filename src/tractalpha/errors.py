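"""Exception hierarchy shared across the package."""


class TractAlphaError(Exception):
    """Base class for all package-specific errors."""


class TractographyFormatError(TractAlphaError, ValueError):
    """A tractography file could not be parsed under the requested dialect."""


class ConfigurationError(TractAlphaError, ValueError):
    """A user-supplied parameter or option combination is invalid."""


class DegenerateGeometryError(TractAlphaError, ValueError):
    """A streamline's geometry prevents a well-defined computation."""


class DomainError(TractAlphaError, ValueError):
    """A numeric input lies outside the documented domain of an operation."""


class EmptyInputError(TractAlphaError, ValueError):
    """An operation that requires data received an empty container."""
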