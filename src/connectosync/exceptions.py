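"""Exception types shared across the pipeline stages."""


class ConnectosyncError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ConnectosyncError):
    """Invalid synthetic-data or pipeline configuration."""


class DegenerateTractError(ConnectosyncError):
    """A tract has no path mass left after trimming to the analysis support."""


class ThresholdError(ConnectosyncError):
    """Connection thresholding is undefined (e.g. all reach probabilities zero)."""


class MappingError(ConnectosyncError):
    """An expression region has no mapping to an atlas ROI."""
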