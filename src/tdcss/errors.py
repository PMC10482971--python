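"""Exception hierarchy shared across the package."""


class TdcssError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(TdcssError, ValueError):
    """A simulation or pipeline configuration field is invalid."""


class SchemaError(TdcssError, ValueError):
    """An input table is missing columns or fails validation."""


class ROIError(TdcssError, ValueError):
    """A well ROI is empty or falls outside the image frame."""


class FitError(TdcssError, RuntimeError):
    """The piecewise onset fit cannot be performed on this trace."""
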