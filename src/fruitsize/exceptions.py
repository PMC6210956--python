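"""Exception hierarchy for the fruit-sizing pipeline.

Pipeline stages raise specific subclasses so that batch processing can map
each failure to a quality-control rejection reason instead of aborting.
"""


class FruitSizeError(Exception):
    """Base class for all fruit-sizing errors."""


class ConfigurationError(FruitSizeError):
    """Invalid camera intrinsics, scene geometry, or pipeline settings."""


class DegenerateInputError(FruitSizeError):
    """An input value (diameter, axis length, ...) is zero, negative, or out of order."""


class UnsupportedImageError(FruitSizeError):
    """Image is not a 3-channel 8-bit RGB raster."""


class NoThresholdError(FruitSizeError):
    """Raster is constant; Otsu's method has no threshold to find."""


class NoReferenceError(FruitSizeError):
    """No circle-like component matching the expected fiducial was found."""


class NoFruitError(FruitSizeError):
    """No component remains to play the fruit role."""


class ContactError(FruitSizeError):
    """Fruit and reference circle touch or have merged into one component."""


class ConvergenceError(FruitSizeError):
    """Iterative depth correction failed to converge."""
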