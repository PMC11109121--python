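"""Exception hierarchy for the CODRP pipeline.

Every error raised on bad input derives from :class:`CodrpError` so callers
(and the CLI) can catch one type and exit with a single-line cause.
"""


class CodrpError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CodrpError):
    """A required column or field is missing from an input table."""


class ValidationError(CodrpError):
    """Input values violate a documented precondition or invariant."""


class ControlError(CodrpError):
    """The DMSO control is unusable (zero or negative mean readout)."""


class ZeroVarianceError(CodrpError):
    """A column to be Z-scored has zero spread across the cohort."""

    def __init__(self, label: str):
        self.label = label
        super().__init__(f"zero variance in column {label!r}: Z-score undefined")


class UndefinedMetricError(CodrpError):
    """A diagnostic metric has an empty denominator."""
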