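"""Exception hierarchy for coldscreen.

All package errors derive from :class:`ColdscreenError` so callers can catch
pipeline failures with a single except clause while letting programming
errors (TypeError etc.) propagate.
"""


class ColdscreenError(Exception):
    """Base class for all coldscreen errors."""


class ParseError(ColdscreenError):
    """A file could not be parsed; the message names the offending row."""


class IntegrityError(ColdscreenError):
    """Parsed data violates a structural invariant (duplicates, bounds, conflicts)."""


class ConfigurationError(ColdscreenError):
    """A configuration object or file is invalid."""


class PlateNormalizationError(ColdscreenError):
    """A plate cannot be median-normalized (no colonies, or median <= 0)."""


class DegenerateDistributionError(ColdscreenError):
    """An outlier threshold cannot be formed (zero spread)."""


class AnalysisError(ColdscreenError):
    """An analysis precondition is not met (too few genes, mismatched screens...)."""
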