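"""Exception hierarchy.

Exit-code mapping used by the CLI: usage errors are handled by click (exit 2),
:class:`DataError` subclasses exit 3, anything else is an internal error (exit 4).
"""


class ConvarError(Exception):
    """Base class for all package errors."""


class DataError(ConvarError):
    """Problem with user-supplied data (unreadable file, bad table, ...)."""


class ImageDecodeError(DataError):
    """A file could not be decoded as a raster image."""


class GeometryError(ConvarError, ValueError):
    """Invalid convolution / pooling geometry (kernel larger than input, ...)."""


class GridError(ConvarError, ValueError):
    """A pooling grid size is incompatible with the response-map geometry."""


class ContractError(ConvarError, ValueError):
    """An operation was called on input violating its stated precondition."""


class ParameterError(ConvarError, ValueError):
    """An out-of-range or inconsistent parameter value."""
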