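"""Exception hierarchy for the feedability screening pipeline."""


class FeedscreenError(Exception):
    """Base class for all feedscreen errors."""


class FormatError(FeedscreenError):
    """A profile file is missing required columns or structure."""


class ParseError(FeedscreenError):
    """A cell in a profile file could not be parsed; names the row."""


class EmptyInputError(FeedscreenError):
    """An input file or collection contained no usable data."""


class DegenerateInputError(FeedscreenError):
    """Input is structurally valid but has no information to work with
    (all-zero force vector, zero-variance profile, single-point phase)."""


class NotTestableError(FeedscreenError):
    """A floppy (sub-trigger) profile reached a stage that requires a
    measurable flexibility profile."""


class GridMismatchError(FeedscreenError):
    """Vectors that must share a distance grid do not."""


class ConfigurationError(FeedscreenError):
    """Invalid protocol, library or panel configuration."""
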