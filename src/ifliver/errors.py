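"""Exception hierarchy for the pipeline.

Every error raised on bad user input derives from :class:`IFLiverError` so
callers (and the CLI) can distinguish pipeline failures from bugs.
"""


class IFLiverError(Exception):
    """Base class for all pipeline errors."""


class FormatError(IFLiverError, ValueError):
    """A file does not conform to its expected tabular format."""


class ValidationError(IFLiverError, ValueError):
    """Inputs are well-formed but semantically invalid."""


class DesignError(IFLiverError, ValueError):
    """The experimental design cannot support the requested analysis
    (e.g. a treatment group with fewer than two arrays)."""


class QCFailureError(IFLiverError, RuntimeError):
    """Quality control would reject so many arrays that the data, not the
    arrays, are suspect."""


class InsufficientDataError(IFLiverError, ValueError):
    """Too few observations for the statistic to be defined."""


class DegenerateDataError(IFLiverError, ValueError):
    """Data carry no usable variation (e.g. all residual variances zero)."""
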