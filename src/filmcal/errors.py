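"""Exception hierarchy for filmcal.

Every error raised by the library derives from :class:`FilmCalError`, so
callers (and the CLI) can distinguish model-domain problems from plain bugs.
"""


class FilmCalError(Exception):
    """Base class for all filmcal errors."""


class DomainError(FilmCalError, ValueError):
    """An input is outside the mathematical domain of an operation."""


class BelowBackgroundError(DomainError):
    """Pixel value below the background level; dose is undefined."""


class SaturationError(DomainError):
    """Pixel value at or beyond saturation; dose is undefined."""


class FitInfeasibleError(FilmCalError):
    """No admissible parameter set is consistent with the data."""


class UnidentifiableError(FitInfeasibleError):
    """The data cannot constrain the requested parameters (e.g. the
    saturation regime was never probed, or dose points are degenerate)."""


class ConfigError(FilmCalError, ValueError):
    """Invalid configuration (method/option combination, generator setup)."""
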