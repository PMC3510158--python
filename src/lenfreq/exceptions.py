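"""Exception hierarchy for lenfreq.

All lenfreq errors derive from :class:`LenfreqError` so callers can catch the
whole family with one clause; the subclasses distinguish configuration
mistakes (bad column names, unknown scenario labels) from data problems
(too few observations, zero spread, invalid length values).
"""


class LenfreqError(Exception):
    """Base class for all lenfreq errors."""


class ConfigurationError(LenfreqError):
    """A user-supplied option is wrong: missing column, unknown scenario, ..."""


class LengthDataError(LenfreqError, ValueError):
    """A length record violates the data invariants (non-numeric, <= 0, ...)."""


class InsufficientDataError(LenfreqError, ValueError):
    """An operation needs more observations than the sample provides."""


class InsufficientSpreadError(LenfreqError, ValueError):
    """A sample has zero spread (SD and IQR both zero); bandwidth selection
    and standardisation are undefined."""
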