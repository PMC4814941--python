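"""Exception hierarchy for the pulsedx pipeline."""


class PulseError(Exception):
    """Base class for all pulsedx errors."""


class FormatError(PulseError):
    """A file does not conform to one of the documented plain-text formats."""


class ParseError(FormatError):
    """A cell in a waveform/manifest file could not be parsed as a number."""


class SegmentationError(PulseError):
    """A channel could not be divided into heart cycles."""


class ExtractionError(PulseError):
    """Subject-level feature extraction failed (one or more channels)."""


class FeatureError(PulseError):
    """Time-domain landmark extraction failed on a degenerate cycle."""


class ConvergenceError(PulseError):
    """An iterative solver did not converge within its sweep budget."""
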