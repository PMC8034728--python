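"""Package-wide exception types."""


class StampError(Exception):
    """Base class for all package errors."""


class FormatError(StampError):
    """Input file violates a structural contract (mixed frame sizes, bad columns)."""


class ValidationError(StampError):
    """In-memory data violates an invariant (out-of-bounds coordinate, bad frame index)."""


class ConfigError(StampError):
    """A configuration value is out of its admissible range."""


class DegenerateInputError(StampError):
    """Input admits no answer (e.g. constant image offered to Otsu thresholding)."""
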