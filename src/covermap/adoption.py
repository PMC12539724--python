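"""County-level zonal accounting and the voluntary-adoption decomposition.

Voluntary acreage is defined as total model-predicted cover-crop acreage
minus government-subsidized acreage, per county-year.  Negative values
(model under-prediction relative to the subsidy ledger) are retained and
flagged, never clamped: the row-wise identity
``total = government + voluntary`` must hold exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import LedgerError, UndefinedStatisticError

log = logging.getLogger(__name__)

LEDGER_COLUMNS = ("county_id", "year", "total_acres", "government_acres",
                  "voluntary_acres", "negative_voluntary")


def zonal_cover_acres(cover_grid: np.ndarray, zones: np.ndarray,
                      pixel_acres: float, year: int) -> pd.DataFrame:
    """Positive-pixel acreage per county zone.

    Zone ids are the positive integers present in ``zones``; id 0 (or
    negative) is treated as outside any county.
    """
    if cover_grid.shape != zones.shape:
        raise LedgerError("cover raster and zone raster are not co-registered")
    ids = np.unique(zones)
    ids = ids[ids > 0]
    counts = np.bincount(zones[cover_grid == 1].ravel(),
                         minlength=int(ids.max()) + 1 if ids.size else 1)
    return pd.DataFrame({
        "county_id": ids.astype(int),
        "year": int(year),
        "acres": [counts[i] * pixel_acres for i in ids],
    })


def _keys(df: pd.DataFrame) -> list[str]:
    return [k for k in ("county_id", "year") if k in df.columns]


def compute_voluntary(total: pd.DataFrame, government: pd.DataFrame) -> pd.DataFrame:
    """Ledger with exact voluntary = total - government per key.

    ``total`` needs an ``acres`` or ``total_acres`` column; ``government``
    an ``acres`` or ``government_acres`` column.  Missing government rows
    count as zero (warned); duplicate keys are an error.
    """
    total = total.rename(columns={"acres": "total_acres"})
    government = government.rename(columns={"acres": "government_acres"})
    keys = _keys(total)
    if not keys or _keys(government) != keys:
        raise LedgerError("total and government tables must share key "
                          "columns (county_id and/or year)")
    for name, df in (("total", total), ("government", government)):
        if df.duplicated(subset=keys).any():
            raise LedgerError(f"duplicate keys in {name} table")
    merged = total.merge(government[keys + ["government_acres"]],
                         on=keys, how="left")
    missing = merged["government_acres"].isna()
    if missing.any():
        log.warning("compute_voluntary: %d county-years missing from the "
                    "government ledger; treated as zero", int(missing.sum()))
        merged["government_acres"] = merged["government_acres"].fillna(0.0)
    merged["voluntary_acres"] = merged["total_acres"] - merged["government_acres"]
    merged["negative_voluntary"] = merged["voluntary_acres"] < 0
    if merged["negative_voluntary"].any():
        log.warning("compute_voluntary: %d rows have negative voluntary "
                    "acreage (flagged, not clamped)",
                    int(merged["negative_voluntary"].sum()))
    return merged


@dataclass
class AdoptionTrends:
    """Yearly totals plus first-to-last change and cumulative acre-years."""

    yearly: pd.DataFrame
    first_year: int
    last_year: int
    voluntary_change_acres: float
    voluntary_change_pct: float
    cumulative_government_acre_years: float
    cumulative_voluntary_acre_years: float
    cumulative_total_acre_years: float


def adoption_trends(ledger: pd.DataFrame) -> AdoptionTrends:
    """Summarize a ledger: yearly sums, percent change on the voluntary
    series between first and last year, cumulative acre-years by source."""
    if "year" not in ledger.columns:
        raise LedgerError("ledger must have a year column")
    cols = ["total_acres", "government_acres", "voluntary_acres"]
    yearly = ledger.groupby("year", as_index=False)[cols].sum().sort_values("year")
    if len(yearly) < 2:
        raise UndefinedStatisticError("trends need at least two years")
    first = yearly.iloc[0]
    last = yearly.iloc[-1]
    if first["voluntary_acres"] == 0:
        raise UndefinedStatisticError("first-year voluntary acreage is zero; "
                                      "percent change undefined")
    change = float(last["voluntary_acres"] - first["voluntary_acres"])
    return AdoptionTrends(
        yearly=yearly.reset_index(drop=True),
        first_year=int(first["year"]),
        last_year=int(last["year"]),
        voluntary_change_acres=change,
        voluntary_change_pct=100.0 * change / float(first["voluntary_acres"]),
        cumulative_government_acre_years=float(ledger["government_acres"].sum()),
        cumulative_voluntary_acre_years=float(ledger["voluntary_acres"].sum()),
        cumulative_total_acre_years=float(ledger["total_acres"].sum()),
    )


def funding_correlation(ledger: pd.DataFrame,
                        level: str = "county_year") -> tuple[float, float, int]:
    """Pearson correlation between government and voluntary acres.

    ``level`` is ``"county_year"`` (each ledger row is an observation) or
    ``"yearly"`` (rows aggregated per year first).  Returns ``(r, p, n)``
    with a two-sided p-value from the t transform.
    """
    if level == "yearly":
        data = ledger.groupby("year", as_index=False)[
            ["government_acres", "voluntary_acres"]].sum()
    elif level == "county_year":
        data = ledger
    else:
        raise ValueError(f"unknown correlation level {level!r}")
    x = data["government_acres"].to_numpy(dtype=float)
    y = data["voluntary_acres"].to_numpy(dtype=float)
    if x.size < 3:
        raise UndefinedStatisticError("correlation needs >= 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError("correlation undefined at zero variance")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), int(x.size)
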