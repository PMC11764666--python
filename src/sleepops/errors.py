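"""Exception types shared across the package."""


class NonFiniteDataError(ValueError):
    """Input signal contains NaN or infinite samples."""


class InvalidDistributionError(ValueError):
    """A probability vector is negative or not normalized within tolerance."""


class DegenerateSignalError(ValueError):
    """Every segment of the series has zero variance, so amplitude-weighted
    probabilities are undefined for q != 0."""

    def __init__(self, message: str, n_segments: int = 0):
        super().__init__(message)
        self.n_segments = n_segments
        self.degenerate = True


class ChannelNotFoundError(KeyError):
    """Requested channel is absent from the signal file."""


class FormatError(IOError):
    """Signal or annotation file could not be parsed."""


class MissingSignalError(RuntimeError):
    """The continuous signal needed to cut an epoch window is unavailable."""


class UnsupportedModelError(TypeError):
    """Operation undefined for this model family (e.g. gain importance for SVM)."""
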