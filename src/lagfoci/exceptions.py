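"""Exception types shared across the package."""


class LagfociError(Exception):
    """Base class for errors raised by this package."""


class FormatError(LagfociError, ValueError):
    """A file does not conform to the declared format."""


class ChannelLookupError(LagfociError, LookupError):
    """A requested channel or montage label cannot be resolved."""


class UndefinedCorrelationError(LagfociError, ValueError):
    """Correlation is undefined because an aligned segment is constant."""


class InsufficientOverlapError(LagfociError, ValueError):
    """Fewer than three sample pairs remain after the lag shift."""


class UndefinedDirectionalityError(LagfociError, ValueError):
    """No lag passes the admissibility filter of the directionality index."""


class InsufficientDataError(LagfociError, ValueError):
    """Too few regime changes to estimate an alternation period."""


class DegenerateGeometryError(LagfociError, ValueError):
    """Electrode geometry does not determine a source position."""


class ConfigError(LagfociError, ValueError):
    """A run configuration is invalid."""
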