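"""Exception hierarchy for baroloop.

All baroloop errors derive from :class:`BaroloopError` so callers can catch
library failures without masking programming errors.
"""


class BaroloopError(Exception):
    """Base class for all baroloop errors."""


class InvalidArgumentError(BaroloopError, ValueError):
    """An argument violates a documented precondition (non-finite, out of range)."""


class NoRootError(BaroloopError):
    """A bracketing solver was given an interval with no sign change."""


class UndefinedRatioError(BaroloopError):
    """A disturbance decomposition was requested for a zero disturbance."""


class InsufficientDataError(BaroloopError):
    """Too few observations for the requested fit or summary."""


class DegenerateDesignError(BaroloopError):
    """Regressor values carry no information (zero variance, coincident points)."""


class NoReflexResponseError(BaroloopError):
    """The fitted pressure-to-norepinephrine slope is non-negative: no reflex."""


class SchemaError(BaroloopError):
    """A study table violates the expected schema; message names the offence."""


class UndefinedTestError(BaroloopError):
    """A paired test was requested where every difference is zero."""
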