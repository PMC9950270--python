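"""Exception hierarchy for spiralpen."""


class SpiralPenError(Exception):
    """Base class for all spiralpen errors."""


class FormatError(SpiralPenError, ValueError):
    """A file does not conform to the recording/metadata CSV dialect."""


class ValidationError(SpiralPenError, ValueError):
    """Data violates an invariant of the recording model (units, gaps, signs)."""


class TooShortError(SpiralPenError, ValueError):
    """A signal is too short for the requested operation."""
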