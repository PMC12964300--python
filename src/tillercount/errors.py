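"""Exception types shared across the package."""


class TillerCountError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(TillerCountError, ValueError):
    """A bundle specification violates its invariants (impossible geometry etc.)."""


class ParameterError(TillerCountError, ValueError):
    """A numeric parameter is out of its valid range."""


class FormatError(TillerCountError, ValueError):
    """An input raster or file has an unsupported layout."""


class PairingError(TillerCountError, ValueError):
    """Bundle sides cannot be paired (a side is missing or duplicated)."""


class UndefinedCorrelationError(TillerCountError, ValueError):
    """Pearson correlation requested for a constant vector."""
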