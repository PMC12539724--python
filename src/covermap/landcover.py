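"""Reclassification of CDL-style rasters, NDVI, and cultivated masking."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, GridError
from .grids import INT_NODATA

log = logging.getLogger(__name__)

#: The seven analysis classes, in legend order.
SEVEN_CLASSES = ("Corn", "Cotton", "Rice", "Sorghum", "Soybean",
                 "Double Crops", "Minor Crops")

#: Classes folded into "Other Crops" at the consolidated level.
CONSOLIDATED_INTO_OTHER = ("Rice", "Sorghum", "Double Crops", "Minor Crops")

CONSOLIDATED_CLASSES = ("Corn", "Cotton", "Soybean", "Other Crops")

#: Default CDL-code table. Fallow/Idle (61) stays in the cropping
#: sequence as Minor Crops; the destination is configurable.
DEFAULT_CODE_TO_CLASS: dict[int, str] = {
    1: "Corn",
    2: "Cotton",
    3: "Rice",
    4: "Sorghum",
    5: "Soybean",
    26: "Double Crops",
    61: "Minor Crops",
}


@dataclass
class ReclassMap:
    """Integer-code -> class-label table with a consolidation level.

    ``consolidation`` is ``"seven_class"`` (the seven labels above) or
    ``"consolidated"`` (Rice/Sorghum/Double/Minor merged into
    "Other Crops").  Codes missing from the table fall back to
    ``default_class`` with a logged warning count.
    """

    code_to_class: dict[int, str] = field(
        default_factory=lambda: dict(DEFAULT_CODE_TO_CLASS))
    consolidation: str = "seven_class"
    default_class: str = "Minor Crops"

    def __post_init__(self) -> None:
        if not self.code_to_class:
            raise ConfigurationError("reclass map must not be empty")
        if self.consolidation not in ("seven_class", "consolidated"):
            raise ConfigurationError(
                f"unknown consolidation level {self.consolidation!r}")

    @property
    def legend(self) -> tuple[str, ...]:
        if self.consolidation == "consolidated":
            return CONSOLIDATED_CLASSES
        labels = list(SEVEN_CLASSES)
        for lab in self.code_to_class.values():
            if lab not in labels:
                labels.append(lab)
        return tuple(labels)

    def label_for(self, code: int) -> str:
        label = self.code_to_class.get(code, self.default_class)
        if self.consolidation == "consolidated" and label in CONSOLIDATED_INTO_OTHER:
            label = "Other Crops"
        return label

    @classmethod
    def from_csv(cls, path, consolidation: str = "seven_class") -> "ReclassMap":
        import pandas as pd

        df = pd.read_csv(path)
        table = dict(zip(df["code"].astype(int), df["label"].astype(str)))
        return cls(code_to_class=table, consolidation=consolidation)


@dataclass
class ClassRaster:
    """A reclassified raster: values index into ``legend`` (nodata kept)."""

    grid: np.ndarray
    year: int
    legend: tuple[str, ...]

    def labels(self) -> np.ndarray:
        """Label array for debugging/reports; nodata rendered as ''."""
        out = np.full(self.grid.shape, "", dtype=object)
        for i, lab in enumerate(self.legend):
            out[self.grid == i] = lab
        return out


def reclassify(raster: np.ndarray, reclass: ReclassMap, year: int = 0) -> ClassRaster:
    """Pixel-wise table lookup from CDL-style codes to class indices.

    Unmapped codes map to the default class; the count is logged so a
    surprising legend does not pass silently.
    """
    legend = reclass.legend
    index = {lab: i for i, lab in enumerate(legend)}
    out = np.full(raster.shape, INT_NODATA, dtype=np.int32)
    known = np.zeros(raster.shape, dtype=bool)
    for code in np.unique(raster):
        if code == INT_NODATA:
            continue
        mapped = reclass.code_to_class.get(int(code))
        out[raster == code] = index[reclass.label_for(int(code))]
        if mapped is not None:
            known |= raster == code
    unmapped = int(((raster != INT_NODATA) & ~known).sum())
    if unmapped:
        log.warning("reclassify: %d pixels had unmapped codes -> %s",
                    unmapped, reclass.default_class)
    return ClassRaster(grid=out, year=year, legend=legend)


def compute_ndvi(red: np.ndarray, nir: np.ndarray) -> np.ndarray:
    """(NIR - Red) / (NIR + Red); NaN where the denominator is zero."""
    if red.shape != nir.shape:
        raise GridError(f"red {red.shape} and nir {nir.shape} differ")
    red = np.asarray(red, dtype=float)
    nir = np.asarray(nir, dtype=float)
    denom = nir + red
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = (nir - red) / denom
    ndvi[denom == 0] = np.nan
    return ndvi


def apply_cultivated_mask(raster: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Set non-cultivated pixels to the nodata sentinel.

    Integer rasters get ``INT_NODATA``; float rasters get NaN.  Retained
    pixels are returned unchanged.
    """
    if raster.shape != mask.shape:
        raise GridError(f"raster {raster.shape} and mask {mask.shape} differ")
    out = raster.copy()
    if np.issubdtype(out.dtype, np.integer):
        out[mask == 0] = INT_NODATA
    else:
        out = out.astype(float)
        out[mask == 0] = np.nan
    return out
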