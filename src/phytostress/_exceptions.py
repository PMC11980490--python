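"""Exception hierarchy shared across the package."""


class PhytostressError(Exception):
    """Base class for all package-specific errors."""


class ParameterizationError(PhytostressError, ValueError):
    """Raised when generator or analysis parameters violate their contract."""


class UndefinedFeatureError(PhytostressError, ValueError):
    """Raised when a feature is undefined for the given input.

    Examples: barycenter of an empty histogram, canopy statistics of an
    empty mask, period of an aperiodic signal.
    """
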