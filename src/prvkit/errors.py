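"""Exception hierarchy for the PRV pipeline.

Every stage raises a subclass of :class:`PRVError`, so callers (and the CLI)
can distinguish pipeline failures from programming errors.
"""


class PRVError(Exception):
    """Base class for all pipeline errors."""


class FormatError(PRVError):
    """Malformed input data (wrong shape, bad CSV, mixed frame sizes)."""


class ParameterError(PRVError):
    """Invalid configuration or out-of-range parameter."""


class NoSkinError(PRVError):
    """A frame contains no pixels inside the configured skin-color bounds."""


class ExtractionQualityError(PRVError):
    """Too many frames without detectable skin for a trustworthy BVP."""


class DegenerateSignalError(PRVError):
    """A signal carries no usable variation (constant input, empty spectrum)."""


class DegenerateSpectrumError(DegenerateSignalError):
    """Spectral indices are undefined (no power outside the VLF band)."""


class SignalTooShortError(PRVError):
    """A signal is shorter than an operation requires."""


class EmptyResultError(PRVError):
    """An operation produced no output (e.g. no peaks detected)."""
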