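"""Exception hierarchy shared across the pipeline stages."""


class PainsenseError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PainsenseError, ValueError):
    """A configuration object has an invalid field; the message names it."""


class ParameterError(PainsenseError, ValueError):
    """A single operation parameter is out of its valid range."""


class EEGIOError(PainsenseError, OSError):
    """Reading or writing an EEG recording failed."""


class UnsupportedDialectError(EEGIOError):
    """The file is recognisable but uses an encoding this reader does not parse."""


class DecodeError(PainsenseError, ValueError):
    """An event id does not encode a pain rating."""


class DomainError(PainsenseError, ValueError):
    """A value (e.g. a pain rating) lies outside its documented domain."""


class BoundsError(PainsenseError, IndexError):
    """An event or window falls outside the recording."""


class LeakageError(PainsenseError, RuntimeError):
    """Test-partition data reached a training-only stage."""


class TrainingError(PainsenseError, ValueError):
    """A model cannot be fitted on the provided data."""


class ShapeError(PainsenseError, ValueError):
    """Array dimensions disagree with what the fitted object expects."""
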