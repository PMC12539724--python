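"""Soil organic carbon (SOC) sequestration model.

A biomass-bookkeeping chain: per-acre above- and belowground cover-crop
biomass is partitioned (a fraction P of aboveground residue stays on the
surface), converted to carbon via the biomass C concentration, and
discounted by microbial (humification) efficiency, yielding tons of C
sequestered.  The per-acre rate R is independent of acreage by
construction, since every intermediate is linear in acres.

With the defaults (AG=3500 lbs/acre, BG=1747 lbs/acre, P=0.30,
Conc=0.50, E=0.50) the rate is 0.524625 tons C/acre/year, printed as
0.52.  Full precision is carried internally; rounding happens only in
report formatting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError

log = logging.getLogger(__name__)

#: kg per (short) ton and m^2-in-hectares per acre; their ratio converts
#: tons/acre to Mg/ha.
KG_PER_TON = 907.18474
HA_PER_ACRE = 0.40468564224
TONS_PER_ACRE_TO_MG_PER_HA = (KG_PER_TON / 1000.0) / HA_PER_ACRE


@dataclass(frozen=True)
class SOCParams:
    """Model constants (lbs/acre for biomass; dimensionless fractions)."""

    AG: float = 3500.0
    BG: float = 1747.0
    P: float = 0.30
    Conc: float = 0.50
    E: float = 0.50
    lbs_per_ton: float = 2000.0

    def __post_init__(self) -> None:
        if self.lbs_per_ton <= 0:
            raise ConfigurationError("lbs_per_ton must be positive")
        if self.AG < 0 or self.BG < 0:
            raise ConfigurationError("biomass amounts must be non-negative")
        for name in ("P", "Conc", "E"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")

    @classmethod
    def from_total_biomass(cls, total_lbs_per_acre: float,
                           ag_fraction: float = 2.0 / 3.0,
                           **kwargs) -> "SOCParams":
        """Alternative parameterization: total biomass plus an
        aboveground fraction (defaults to the 2/3 : 1/3 split)."""
        return cls(AG=ag_fraction * total_lbs_per_acre,
                   BG=(1.0 - ag_fraction) * total_lbs_per_acre, **kwargs)


def soc_rate(params: SOCParams = SOCParams()) -> float:
    """Sequestration rate R in tons C/acre/year.

    Equals the full chain evaluated at one acre:
    ((AG*(1-P)) + BG) * Conc * E / lbs_per_ton.
    """
    incorporated = params.AG * (1.0 - params.P)
    return (incorporated + params.BG) * params.Conc * params.E / params.lbs_per_ton


def soc_chain(acres, params: SOCParams = SOCParams()) -> pd.DataFrame:
    """Every intermediate of the model for the given acreages (tons).

    Columns: cca, t_ag, t_bg, t_ag_bg, i_ag, t_bs, c_s, t_scm, rate.
    """
    cca = np.asarray(acres, dtype=float)
    t_ag = params.AG * cca / params.lbs_per_ton
    t_bg = params.BG * cca / params.lbs_per_ton
    i_ag = t_ag * (1.0 - params.P)
    t_bs = t_bg + i_ag
    c_s = t_bs * params.Conc
    t_scm = c_s * params.E
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(cca > 0, t_scm / cca, soc_rate(params))
    return pd.DataFrame({
        "cca": cca, "t_ag": t_ag, "t_bg": t_bg, "t_ag_bg": t_ag + t_bg,
        "i_ag": i_ag, "t_bs": t_bs, "c_s": c_s, "t_scm": t_scm, "rate": rate,
    })


def soc_table(acreage: pd.DataFrame,
              params: SOCParams = SOCParams()) -> pd.DataFrame:
    """Per-year SOC tonnage by funding source.

    ``acreage`` needs a ``year`` column plus any of ``government_acres``,
    ``voluntary_acres``, ``total_acres``.  Rows with negative acres in a
    column are excluded from that column's SOC (NaN) with a warning.
    """
    if "year" not in acreage.columns:
        raise ValueError("acreage table must have a year column")
    sources = [c for c in ("government_acres", "voluntary_acres", "total_acres")
               if c in acreage.columns]
    if not sources:
        raise ValueError("no acreage columns found")
    rate = soc_rate(params)
    out = acreage[["year"] + sources].copy()
    for col in sources:
        acres = out[col].to_numpy(dtype=float)
        negative = acres < 0
        if negative.any():
            log.warning("soc_table: %d negative rows in %s excluded from SOC",
                        int(negative.sum()), col)
        soc = np.where(negative, np.nan, acres * rate)
        out[col.replace("_acres", "_soc_tons")] = soc
    return out


def convert_rate(rate: float, to: str = "mg_per_ha") -> float:
    """Convert tons/acre/year <-> Mg/ha/year (factor 2.2417)."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if to == "mg_per_ha":
        return rate * TONS_PER_ACRE_TO_MG_PER_HA
    if to == "tons_per_acre":
        return rate / TONS_PER_ACRE_TO_MG_PER_HA
    raise ValueError(f"unknown target unit {to!r}")


def literature_rates() -> pd.DataFrame:
    """Published cover-crop SOC accrual rates for side-by-side reporting.

    Rates in tons C/acre/year; ``sd`` is the reported spread where one
    was given, NaN otherwise.
    """
    rows = [
        ("Poeplau & Don", 0.14, 0.04, "meta-analysis, 0-11.8 in"),
        ("Ruis & Blanco-Canqui", 0.22, np.nan, "review, 0-11.8 in"),
        ("Jian et al.", 0.24, np.nan, "meta-analysis, varying depths"),
        ("Blanco-Canqui (US, SOC-positive cases)", 0.25, np.nan,
         "US review, mean of 22 increases"),
        ("Blanco-Canqui (US, all comparisons)", 0.21, np.nan,
         "US review, 77 comparisons, upper 30 in"),
        ("Causarano et al. (no-till + cover crops)", 0.30, 0.28,
         "southeastern US cotton systems"),
        ("Causarano et al. (no-till only)", 0.15, 0.21,
         "southeastern US cotton systems"),
    ]
    return pd.DataFrame(rows, columns=["source", "rate", "sd", "context"])
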