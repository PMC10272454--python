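"""Exception hierarchy shared across the pipeline stages."""


class TexchangeError(Exception):
    """Base class for all texchange errors."""


class ParameterError(TexchangeError, ValueError):
    """Invalid model or configuration parameters."""


class ResolutionError(TexchangeError, ValueError):
    """Grid spacing too coarse to resolve the requested spectrum."""


class DegenerateInputError(TexchangeError, ValueError):
    """Input with no usable variance / no valid samples."""


class GeometryError(TexchangeError, ValueError):
    """Mismatched physical extents between fields."""


class RateError(TexchangeError, ValueError):
    """Incompatible sample rates."""


class BoundsError(TexchangeError, IndexError):
    """Requested window falls outside the recording."""
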