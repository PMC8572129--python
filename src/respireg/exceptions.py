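"""Exception hierarchy for respireg.

All pipeline errors derive from :class:`RespiregError` so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class RespiregError(Exception):
    """Base class for all respireg errors."""


class ConfigError(RespiregError, ValueError):
    """Invalid configuration (e.g. breathing amplitude too large)."""


class FormatError(RespiregError, ValueError):
    """Malformed or inconsistent on-disk dataset."""


class DegenerateInputError(RespiregError, ValueError):
    """Input on which the operation is mathematically undefined.

    Examples: Otsu on a constant region, entropy of an empty mask,
    coefficient of variation of a zero-mean sample.
    """


class SegmentationError(RespiregError, RuntimeError):
    """Segmentation could not produce a usable mask."""


class RegistrationError(RespiregError, RuntimeError):
    """No usable candidate slice (or no usable slice in a phase)."""
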