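class AFCNetError(Exception):
    """Base class for package errors."""


class ConfigurationError(AFCNetError):
    """Invalid block/model/training configuration."""


class ShapeError(AFCNetError):
    """Tensor shapes incompatible with an operation's contract."""


class NumericError(AFCNetError):
    """Non-finite values appeared where finiteness is guaranteed."""


class GenerationError(AFCNetError):
    """Synthetic-sample generation failed within the retry budget."""
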