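"""Exception hierarchy shared across the pipeline."""


class AcghError(Exception):
    """Base class for all pipeline errors."""


class ParseError(AcghError):
    """A file could not be parsed; message carries the offending line number."""


class ValidationError(AcghError):
    """An object violates a structural invariant (ordering, ranges, uniqueness)."""


class ConfigError(AcghError):
    """Invalid configuration or simulation parameters."""


class DegenerateFitError(AcghError):
    """Model fit requested on data that cannot support it (e.g. K > distinct values)."""


class DegenerateCalibrationError(AcghError):
    """Threshold calibration on data with no spread."""


class UndefinedFgaError(AcghError):
    """FGA requested for a profile with zero informative clones."""


class JoinError(AcghError):
    """Tables that must share sample_ids do not."""
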