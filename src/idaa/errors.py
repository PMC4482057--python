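"""Exception hierarchy for the idaa toolkit.

Every error raised deliberately by the library derives from :class:`IdaaError`
so callers (and the CLI) can distinguish tool errors from programming bugs.
"""


class IdaaError(Exception):
    """Base class for all idaa errors."""


class AbifFormatError(IdaaError):
    """File is not an ABIF container (bad magic or unparsable header)."""


class AbifCorruptionError(IdaaError):
    """ABIF directory or data block is truncated or inconsistent."""


class IntensityRangeError(IdaaError, ValueError):
    """Trace intensities fall outside the signed 16-bit range."""


class ParameterError(IdaaError, ValueError):
    """A processing parameter is outside its documented range."""


class LadderFailureError(IdaaError):
    """Size-standard peaks could not be matched; the sample cannot be sized."""


class ReferenceSizeError(IdaaError):
    """Wild-type reference size could not be established unambiguously."""


class UndefinedResultError(IdaaError):
    """A quantity (e.g. cutting efficiency) is undefined for empty input."""


class DesignError(IdaaError):
    """Primer/amplicon design is inconsistent with the reference sequence."""


class SequenceValidationError(IdaaError, ValueError):
    """A nucleotide sequence contains characters outside its alphabet."""


class SimulationSpecError(IdaaError, ValueError):
    """A simulation specification is internally inconsistent."""


class ConfigError(IdaaError):
    """Run configuration is invalid."""
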