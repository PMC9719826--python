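"""Exception hierarchy shared across the package."""


class GCAnnotateError(Exception):
    """Base class for all package-specific errors."""


class FormulaError(GCAnnotateError, ValueError):
    """Malformed or empty molecular formula."""


class FormatError(GCAnnotateError, ValueError):
    """A file did not conform to its declared text format."""


class ConfigError(GCAnnotateError, ValueError):
    """Invalid or incomplete configuration."""


class ContractError(GCAnnotateError, ValueError):
    """An operation was called with inputs violating its contract."""


class UndefinedScoreError(GCAnnotateError, ValueError):
    """A similarity score is undefined (all-zero weighted vector)."""


class ResolutionError(GCAnnotateError, ValueError):
    """An accurate-mass operation received a unit-resolution spectrum."""


class OutOfRangeError(GCAnnotateError, ValueError):
    """Retention time outside the alkane calibration span."""


class MissingRIError(GCAnnotateError, ValueError):
    """Retention-index comparison requested but no library RI is available."""


class InsufficientStandardError(GCAnnotateError, ValueError):
    """A reference standard lacks both reference peaks and an in-house spectrum."""
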