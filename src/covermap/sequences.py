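"""Pixel-wise combine of categorical layers and sequence-pattern accounting.

Three analyses are supported for each year t:

* cash crop (t) -> cover state (t)           — 2-way
* cover state (t) -> cash crop (t+1)         — 2-way
* cash crop (t) -> cover state (t) -> cash crop (t+1)  — 3-way

where the cover layer for year t describes the winter bridging t and
t+1.  A pixel enters a table only if every input layer is valid there;
nodata in any layer removes the pixel from both numerator and
denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GridError
from .grids import INT_NODATA

log = logging.getLogger(__name__)

#: Legend of the binary cover layer (value 0, value 1).
COVER_LEGEND = ("None", "CC")

#: Separator used to render pattern labels ("Soybean – CC – Soybean").
LABEL_SEP = " – "


@dataclass
class PatternTable:
    """Per-pattern pixel counts, acres and share of accountable cropland.

    ``table`` columns: pattern_id, label, elements (tuple of labels),
    pixels, acres, pct.  Sorted by acres descending, ties broken
    lexicographically by label.
    """

    table: pd.DataFrame
    total_pixels: int
    total_acres: float

    def top(self, k: int | None = None) -> pd.DataFrame:
        if k is None or k >= len(self.table):
            return self.table
        return self.table.head(k)

    def suppress(self, min_acres: float) -> "PatternTable":
        """Drop rows below a reporting threshold (denominator unchanged)."""
        kept = self.table[self.table["acres"] >= min_acres].reset_index(drop=True)
        return PatternTable(kept, self.total_pixels, self.total_acres)


def enumerate_patterns(n_classes: int, n_states: int,
                       n_classes_after: int | None = None) -> int:
    """Number of distinct sequence patterns (product of arities)."""
    if n_classes < 1 or n_states < 1 or (
            n_classes_after is not None and n_classes_after < 1):
        raise ValueError("all counts must be >= 1")
    total = n_classes * n_states
    if n_classes_after is not None:
        total *= n_classes_after
    return total


def combine(rasters: list[np.ndarray], legends: list[tuple[str, ...]],
            pixel_acres: float) -> tuple[np.ndarray, PatternTable]:
    """Cross-tabulate 2-3 co-registered categorical rasters.

    Equivalent to an exhaustive per-pixel nested tally: every unique
    value tuple over valid pixels becomes a pattern.  Returns the
    pattern-id raster (nodata where any input is nodata) and the table.
    """
    if not 2 <= len(rasters) <= 3:
        raise ValueError(f"combine takes 2 or 3 rasters, got {len(rasters)}")
    if len(legends) != len(rasters):
        raise ValueError("one legend per raster required")
    shape = rasters[0].shape
    for r in rasters[1:]:
        if r.shape != shape:
            raise GridError("combine inputs are not co-registered")

    valid = np.ones(shape, dtype=bool)
    for r in rasters:
        valid &= r != INT_NODATA
    stacked = np.stack([r[valid] for r in rasters], axis=1)
    tuples, inverse, counts = np.unique(stacked, axis=0, return_inverse=True,
                                        return_counts=True)
    total_pixels = int(valid.sum())

    rows = []
    for i, (combo, n) in enumerate(zip(tuples, counts)):
        elements = tuple(legends[j][int(v)] for j, v in enumerate(combo))
        rows.append(dict(label=LABEL_SEP.join(elements), elements=elements,
                         pixels=int(n), acres=float(n) * pixel_acres))
    table = pd.DataFrame(rows)
    table["pct"] = 100.0 * table["pixels"] / total_pixels if total_pixels else 0.0
    order = table.sort_values(["acres", "label"],
                              ascending=[False, True],
                              kind="mergesort").index.to_numpy()
    table = table.loc[order].reset_index(drop=True)
    table.insert(0, "pattern_id", np.arange(len(table)))

    # Remap per-pixel group ids onto the sorted table order.
    rank = np.empty(len(order), dtype=np.int32)
    rank[order] = np.arange(len(order), dtype=np.int32)
    pattern_raster = np.full(shape, INT_NODATA, dtype=np.int32)
    pattern_raster[valid] = rank[inverse]

    return pattern_raster, PatternTable(
        table=table, total_pixels=total_pixels,
        total_acres=total_pixels * pixel_acres)


def rotation_report(years, class_rasters, cover_rasters, pixel_acres: float,
                    top_k: int | None = None) -> dict[str, dict[int, PatternTable]]:
    """Run the three sequence analyses for every available year.

    ``class_rasters`` maps year -> :class:`~covermap.landcover.ClassRaster`;
    ``cover_rasters`` maps year -> binary cover array (0/1, nodata
    sentinel elsewhere).  Years lacking a t+1 class raster only get the
    crop->cover analysis, with a logged warning.
    """
    report: dict[str, dict[int, PatternTable]] = {
        "crop_cc": {}, "cc_crop": {}, "crop_cc_crop": {}}
    years = sorted(years)
    for t in years:
        cls_t = class_rasters[t]
        cover_t = cover_rasters[t]
        _, tbl = combine([cls_t.grid, cover_t],
                         [cls_t.legend, COVER_LEGEND], pixel_acres)
        report["crop_cc"][t] = tbl
        if t + 1 not in class_rasters:
            log.warning("rotation_report: no year %d raster; forward "
                        "analyses truncated at %d", t + 1, t)
            continue
        cls_next = class_rasters[t + 1]
        _, tbl = combine([cover_t, cls_next.grid],
                         [COVER_LEGEND, cls_next.legend], pixel_acres)
        report["cc_crop"][t] = tbl
        _, tbl = combine([cls_t.grid, cover_t, cls_next.grid],
                         [cls_t.legend, COVER_LEGEND, cls_next.legend],
                         pixel_acres)
        report["crop_cc_crop"][t] = tbl
    if top_k is not None:
        report = {name: {y: PatternTable(tbl.top(top_k), tbl.total_pixels,
                                         tbl.total_acres)
                         for y, tbl in per_year.items()}
                  for name, per_year in report.items()}
    return report


def tidy_tables(per_year: dict[int, PatternTable]) -> pd.DataFrame:
    """Stack per-year tables into one tidy frame (year, label, acres, pct)."""
    frames = []
    for year, tbl in sorted(per_year.items()):
        df = tbl.table[["label", "pixels", "acres", "pct"]].copy()
        df.insert(0, "year", year)
        frames.append(df)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["year", "label", "pixels", "acres", "pct"])
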