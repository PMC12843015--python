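"""Exception hierarchy for corrisk.

All errors raised by the public API derive from :class:`CorriskError`, so
callers (including the CLI) can catch one base class.
"""


class CorriskError(Exception):
    """Base class for all corrisk errors."""


class TableValidationError(CorriskError, ValueError):
    """A 3x2 table failed validation (negative/non-integer cell, zero row total,
    wrong shape, malformed file)."""


class DegenerateTableError(CorriskError, ValueError):
    """A statistic is undefined on this table (e.g. a zero event count makes a
    log relative risk infinite)."""


class DegenerateVarianceError(CorriskError, ValueError):
    """The variance of the log-difference is not positive, so the standardized
    statistic is undefined."""
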