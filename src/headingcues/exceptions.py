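"""Exception hierarchy for headingcues.

All package-specific errors derive from :class:`HeadingCuesError` so callers
can catch everything with one clause; the subclasses distinguish the failure
modes the analysis can hit (exhausted staircases, unidentifiable psychometric
fits, degenerate resamples, incomplete condition designs).
"""


class HeadingCuesError(Exception):
    """Base class for all headingcues errors."""


class StaircaseExhaustedError(HeadingCuesError):
    """An adaptive staircase was updated after its trial budget was spent."""


class UnidentifiableFitError(HeadingCuesError):
    """The psychometric likelihood has no interior maximum.

    Raised when all responses are identical (sigma is unbounded) or when
    fewer than two distinct headings were presented.
    """


class DegenerateDataError(HeadingCuesError):
    """More than half of bootstrap resamples were unidentifiable."""


class DegenerateSeparationError(HeadingCuesError):
    """Unisensory PSEs coincide; empirical cue weights are unidentifiable."""


class IncompleteDesignError(HeadingCuesError):
    """A summary requires conditions that are missing from the dataset."""
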