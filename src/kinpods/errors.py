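"""Exception hierarchy for kinpods.

All package-specific failures derive from :class:`KinpodsError` so callers can
catch the whole family; contract violations on arguments raise ``ValueError``
subclasses so they also behave like ordinary Python argument errors.
"""


class KinpodsError(Exception):
    """Base class for all kinpods errors."""


class ParseError(KinpodsError):
    """A data file could not be parsed; the message names the offending line."""


class ValidationError(KinpodsError):
    """Parsed data violates a dataset invariant (duplicate id, half-typed locus)."""


class ArgumentError(KinpodsError, ValueError):
    """An argument is outside its documented domain."""


class InsufficientDataError(KinpodsError):
    """Too few typed loci, pairs, or individuals to compute the quantity."""


class UndefinedEstimateError(KinpodsError):
    """Every locus was degenerate for this dyad; the estimate does not exist."""


class UntestableError(KinpodsError):
    """The requested hypothesis test has no valid null (e.g. one haplotype only)."""


class CalibrationError(KinpodsError):
    """Simulated relatedness distributions are too overlapped to place thresholds."""


class GenerationError(KinpodsError):
    """A requested synthetic composition cannot be built from the pedigree."""


class PipelineError(KinpodsError):
    """A pipeline stage failed; the message names the stage."""
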