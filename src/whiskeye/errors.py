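"""Exception hierarchy shared across the pipeline."""


class WhiskeyeError(Exception):
    """Base class for all package errors."""


class ConfigError(WhiskeyeError, ValueError):
    """Invalid configuration value; message names the offending field."""


class FormatError(WhiskeyeError, ValueError):
    """Malformed on-disk artifact."""


class FitError(WhiskeyeError, ValueError):
    """Degenerate input to a geometric fit."""


class GeometryError(WhiskeyeError, ValueError):
    """Geometrically impossible configuration (e.g. non-crossing eyelids)."""


class AnalysisError(WhiskeyeError, ValueError):
    """Invalid input to an analysis stage."""
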