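"""Exception hierarchy shared across the package."""


class WsiSamplerError(Exception):
    """Base class for all package errors."""


class ParameterError(WsiSamplerError, ValueError):
    """A parameter is outside its documented domain."""


class DimensionError(WsiSamplerError, ValueError):
    """Slide or grid dimensions are invalid or too small."""


class BoundsError(WsiSamplerError, IndexError):
    """A coordinate falls outside the slide's half-open bounds."""


class FormatError(WsiSamplerError, ValueError):
    """A serialized slide or annotation file is malformed."""


class DegenerateSlideError(WsiSamplerError, ValueError):
    """A slide lacks the tissue content a computation requires."""


class UndefinedMetricError(WsiSamplerError, ValueError):
    """A metric's denominator is empty (e.g. no tumour or stroma samples)."""


class ConfigurationError(WsiSamplerError, ValueError):
    """A classifier or pipeline configuration is inconsistent."""


class InputError(WsiSamplerError, ValueError):
    """Inputs to an aggregate operation are missing or mismatched."""
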