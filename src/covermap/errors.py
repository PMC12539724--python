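"""Exception hierarchy shared across the package."""


class CovermapError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CovermapError):
    """Invalid configuration value (bad rotation matrix, empty map, ...)."""


class GridError(CovermapError):
    """Raster grids are not co-registered (shape/geometry mismatch)."""


class DegenerateSceneError(CovermapError):
    """A generated scene has no usable content (e.g. zero cultivated pixels)."""


class EmptyTrainingError(CovermapError):
    """All cover-labeled training points were filtered out."""


class StratificationError(CovermapError):
    """A label class is too small to split into train/validation."""


class DegenerateModelError(CovermapError):
    """Training data contains a single label; no classifier can be fit."""


class LedgerError(CovermapError):
    """County-year ledger is malformed (duplicate keys, missing columns)."""


class UndefinedStatisticError(CovermapError):
    """A requested statistic is undefined for the given data (zero variance,
    zero baseline, too few observations)."""
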