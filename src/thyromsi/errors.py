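"""Exception hierarchy shared across the pipeline."""


class ThyromsiError(Exception):
    """Base class for all package errors."""


class ParameterError(ThyromsiError, ValueError):
    """Invalid configuration value or operation parameter."""


class FormatError(ThyromsiError, ValueError):
    """Malformed input file (imzML/ibd pair, manifest or ROI CSV)."""


class RoiValidationError(ThyromsiError, ValueError):
    """ROI annotation violates raster bounds or the non-overlap invariant."""


class InadequateSampleError(ThyromsiError, ValueError):
    """Sample has no retained spectra/ROIs and cannot be diagnosed."""


class NoFeaturesError(ThyromsiError, ValueError):
    """Peak binning received no peaks; no feature axis can be built."""
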