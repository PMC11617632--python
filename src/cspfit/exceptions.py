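"""Exception hierarchy.

Exit-code mapping in the CLI: DataError subclasses -> 1, ConfigError -> 2.
"""


class CspfitError(Exception):
    """Base class for all package errors."""


class DataError(CspfitError):
    """A problem with the input data (format, consistency, quality)."""


class ConfigError(CspfitError):
    """A problem with configuration or parameters."""


class PeakListFormatError(DataError):
    """Malformed peak list: missing column, bad value, unknown dialect."""


class DuplicatePeakError(DataError):
    """Two peaks with the same (probe, form) in one list."""


class ManifestError(DataError):
    """Invalid titration manifest (no apo point, nonmonotone ratios, ...)."""


class InsufficientDataError(DataError):
    """Too few titration points (or probes) for the requested fit."""


class UnidentifiableKdError(DataError):
    """All titration points saturated; K_D cannot be determined.

    The remedy is to repeat the titration at lower ligand:protein ratios.
    """


class FitConvergenceError(DataError):
    """The nonlinear optimiser failed to converge."""


class DegenerateInputError(DataError):
    """Input with no usable variance (e.g. constant regressor)."""


class DataQualityError(DataError):
    """Data inconsistent with the assumed model beyond noise."""


class AmbiguousRegimeError(DataError):
    """Series mixes merged and free/bound forms; regime must be given."""
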