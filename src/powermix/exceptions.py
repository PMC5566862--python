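"""Exception hierarchy used across powermix.

All errors raised by the library derive from :class:`PowermixError` so that
callers (and the CLI) can catch one base class.
"""


class PowermixError(Exception):
    """Base class for all powermix errors."""


class SchemaError(PowermixError, ValueError):
    """A tabular input does not follow the documented CSV schema."""


class ParseError(SchemaError):
    """A cell could not be parsed; the message names the offending row."""


class DomainError(PowermixError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class DegenerateDesignError(DomainError):
    """A study design produces expected cell counts below the floor."""


class ConfigurationError(PowermixError, ValueError):
    """A configuration object is inconsistent or incomplete."""


class ResolutionError(PowermixError, RuntimeError):
    """A numerical grid was too coarse to achieve the requested accuracy."""
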