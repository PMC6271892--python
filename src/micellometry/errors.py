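"""Exception hierarchy.

Every reader and every numerical stage raises a subclass of
:class:`MicellometryError`, so callers (and the CLI) can distinguish
malformed input (exit code 2) from numerical failure (exit code 3).
"""


class MicellometryError(Exception):
    """Base class for all package errors."""


class InputError(MicellometryError):
    """Malformed, empty or otherwise invalid input data."""


class ParseError(InputError):
    """A file could not be parsed; the message names the offending line."""


class FormatError(InputError):
    """Unrecognized file format or dialect."""


class GeometryError(InputError):
    """Geometrically impossible parameters (e.g. core radius >= shell)."""


class PackingError(MicellometryError):
    """A stochastic placement could not satisfy its clash constraints."""


class StateError(MicellometryError):
    """An operation applied to a curve in the wrong smearing/scaling state."""


class NumericalError(MicellometryError):
    """A fit or transform failed or is not identifiable on this input."""
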