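"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`VibmatchError`, so callers (and the CLI) can distinguish domain
failures from programming errors.
"""


class VibmatchError(Exception):
    """Base class for all package errors."""


class FormatError(VibmatchError):
    """A file does not conform to the expected on-disk dialect."""


class ValidationError(VibmatchError):
    """A domain invariant is violated (bad frequency, unnormalized input...)."""


class InsufficientDataError(VibmatchError):
    """Too few data points for the requested statistic or fit."""


class ClassificationError(VibmatchError):
    """A vibrational feature cannot be assigned to a mode class."""
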