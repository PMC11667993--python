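"""Exception hierarchy for fidgetquant."""


class FidgetQuantError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FidgetQuantError, ValueError):
    """A parameter or config value is invalid (bad ROI, d > rate, ...)."""


class FormatError(FidgetQuantError, ValueError):
    """Input data has the wrong shape, dtype or channel count."""


class InsufficientFootageError(FidgetQuantError, IOError):
    """A session is shorter than the requested analysis clip.

    Raised instead of silently padding: a short recording would bias every
    downstream per-second count.
    """


class EmptySeriesError(FidgetQuantError, ValueError):
    """An operation received an empty movement series or mask stack."""
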