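"""Exception hierarchy.

Exit-code mapping used by the CLI: :class:`DataError` subclasses → 1,
:class:`ConfigError` subclasses → 2.
"""


class BiodosimError(Exception):
    """Base class for all package errors."""


class DataError(BiodosimError):
    """Problems with input data content (CLI exit code 1)."""


class InvalidInputError(DataError, ValueError):
    """A scalar argument violates a physical precondition (mass ≤ 0, ...)."""


class SchemaError(DataError):
    """A delimited-text input violates the documented column schema."""


class FitError(DataError):
    """A time-activity curve cannot be fitted (too few positive points, ...)."""


class MappingError(DataError):
    """A study organ cannot be mapped onto the phantom's organ list."""


class DosimetryError(DataError):
    """Residence times and S values cannot be combined into doses."""


class ConfigError(BiodosimError):
    """Invalid configuration: unknown labels, bad kinetic specs (exit code 2)."""


class ExtrapolationError(ConfigError):
    """A query lies outside the supported grid range and extrapolation is off."""
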