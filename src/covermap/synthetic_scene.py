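"""Synthetic scene generator.

Builds co-registered multi-year categorical crop rasters with rotation
structure, winter red/NIR reflectance layers whose NDVI separates
cover-cropped from bare pixels, ground-truth points with a controllable
fraction of mislocated (off-field) points, a county zone map, and a
county-year subsidized-acreage ledger.  Everything downstream of real
satellite and survey inputs can therefore be exercised offline.

All randomness flows from ``SceneConfig.seed`` through
``numpy.random.default_rng``; regeneration with the same config is
bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Polygon, box

from .errors import ConfigurationError, DegenerateSceneError
from .grids import INT_NODATA, GridSpec

#: Default CDL-style code -> label table (7 analysis codes).
DEFAULT_CROP_CODES: dict[int, str] = {
    1: "Corn",
    2: "Cotton",
    3: "Rice",
    4: "Sorghum",
    5: "Soybean",
    26: "Double Crops",
    61: "Minor Crops",
}


def _default_rotation_matrix(n: int) -> np.ndarray:
    """Sticky rotation: stay with probability 0.55, else move uniformly."""
    m = np.full((n, n), 0.45 / (n - 1))
    np.fill_diagonal(m, 0.55)
    return m


@dataclass(frozen=True)
class NDVIParams:
    """Winter NDVI distributions for covered vs bare pixels.

    Defaults put >4 standard deviations between each mean and the 0.3
    decision threshold, so a noiseless-threshold reading of the scene
    recovers the truth almost everywhere.
    """

    cover_mean: float = 0.65
    cover_sd: float = 0.08
    bare_mean: float = 0.12
    bare_sd: float = 0.06


@dataclass
class SceneConfig:
    n_rows: int = 100
    n_cols: int = 100
    pixel_size_m: float = 30.0
    years: tuple[int, ...] = (2013, 2014, 2015)
    n_counties: int = 4
    crop_codes: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_CROP_CODES))
    rotation_matrix: np.ndarray | None = None
    cc_adoption_rate: float | dict[int, float] = 0.3
    subsidized_fraction: float = 0.25
    contamination_rate: float = 0.1
    cultivated_fraction: float = 0.85
    n_truth_points: int = 200
    ndvi_params: NDVIParams = field(default_factory=NDVIParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_m <= 0:
            raise ConfigurationError("pixel_size_m must be positive")
        if list(self.years) != sorted(set(self.years)):
            raise ConfigurationError("years must be strictly increasing")
        if self.n_counties < 1:
            raise ConfigurationError("n_counties must be >= 1")
        if not self.crop_codes:
            raise ConfigurationError("crop_codes must not be empty")
        rates = [self.subsidized_fraction, self.contamination_rate,
                 self.cultivated_fraction]
        if isinstance(self.cc_adoption_rate, dict):
            rates += list(self.cc_adoption_rate.values())
        else:
            rates.append(self.cc_adoption_rate)
        for r in rates:
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError(f"rate {r} outside [0, 1]")
        if self.rotation_matrix is None:
            self.rotation_matrix = _default_rotation_matrix(len(self.crop_codes))
        m = np.asarray(self.rotation_matrix, dtype=float)
        k = len(self.crop_codes)
        if m.shape != (k, k):
            raise ConfigurationError(
                f"rotation_matrix must be {k}x{k}, got {m.shape}")
        if np.any(m < 0) or not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigurationError("rotation_matrix rows must be >=0 and sum to 1")
        self.rotation_matrix = m

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.n_rows, self.n_cols, self.pixel_size_m)

    def adoption_rate_for(self, code: int) -> float:
        if isinstance(self.cc_adoption_rate, dict):
            return self.cc_adoption_rate.get(code, 0.0)
        return self.cc_adoption_rate


@dataclass
class SyntheticScene:
    """Co-registered synthetic inputs for one run.

    ``crop_rasters[year]`` holds CDL-style integer codes; ``cc_truth``,
    ``red`` and ``nir`` are indexed by the year whose winter they
    describe (winter bridging ``year`` and ``year + 1``).
    """

    config: SceneConfig
    grid: GridSpec
    crop_rasters: dict[int, np.ndarray]
    cultivated_mask: np.ndarray
    cc_truth: dict[int, np.ndarray]
    red: dict[int, np.ndarray]
    nir: dict[int, np.ndarray]
    county_zones: np.ndarray
    county_polygons: dict[int, Polygon]
    truth_points: pd.DataFrame
    nrcs_ledger: pd.DataFrame | None = None

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(self.config.years)

    def ndvi(self, year: int) -> np.ndarray:
        red, nir = self.red[year], self.nir[year]
        return (nir - red) / (nir + red)

    def true_cover_acres(self, year: int) -> float:
        return float(self.cc_truth[year].sum()) * self.grid.pixel_acres

    def true_cover_acres_by_county(self, year: int) -> pd.DataFrame:
        ids = np.unique(self.county_zones)
        counts = np.bincount(
            self.county_zones[self.cc_truth[year] == 1].ravel(),
            minlength=ids.max() + 1)
        return pd.DataFrame({
            "county_id": ids,
            "year": year,
            "acres": counts[ids] * self.grid.pixel_acres,
        })


def _county_zones(spec: GridSpec, n_counties: int) -> tuple[np.ndarray, dict[int, Polygon]]:
    """Vertical-strip counties; ids start at 1."""
    edges = np.linspace(0, spec.n_cols, n_counties + 1).round().astype(int)
    zones = np.zeros(spec.shape, dtype=np.int32)
    polys: dict[int, Polygon] = {}
    for i in range(n_counties):
        zones[:, edges[i]:edges[i + 1]] = i + 1
        polys[i + 1] = box(
            spec.x_origin + edges[i] * spec.pixel_size,
            spec.y_origin,
            spec.x_origin + edges[i + 1] * spec.pixel_size,
            spec.y_origin + spec.n_rows * spec.pixel_size,
        )
    return zones, polys


def _truncnorm_draw(rng: np.random.Generator, mean: float, sd: float,
                    size: int) -> np.ndarray:
    """NDVI draw truncated to the physical range [-1, 1]."""
    if sd == 0:
        return np.full(size, mean)
    a, b = (-1.0 - mean) / sd, (1.0 - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _reflectance_from_ndvi(rng: np.random.Generator,
                           ndvi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solve (red, nir) so that (nir-red)/(nir+red) equals the drawn NDVI.

    The brightness nir+red is drawn in [0.3, 0.7], keeping both bands in
    [0, 1] for any NDVI in [-1, 1].
    """
    total = rng.uniform(0.3, 0.7, size=ndvi.shape)
    nir = total * (1.0 + ndvi) / 2.0
    red = total * (1.0 - ndvi) / 2.0
    return red, nir


def _sample_truth_points(rng: np.random.Generator, scene_cfg: SceneConfig,
                         spec: GridSpec, cultivated: np.ndarray,
                         truth: np.ndarray, year: int) -> pd.DataFrame:
    """Half cover / half none points for one winter, with contamination.

    Contaminated points keep their "cover" label but are displaced onto a
    non-cultivated pixel (mimicking GPS fixes taken at the farmstead).
    """
    n = scene_cfg.n_truth_points
    cover_idx = np.flatnonzero((cultivated == 1) & (truth == 1))
    none_idx = np.flatnonzero((cultivated == 1) & (truth == 0))
    off_idx = np.flatnonzero(cultivated == 0)
    n_cover = min(n // 2, cover_idx.size)
    n_none = min(n - n // 2, none_idx.size)
    rows: list[dict] = []
    chosen_cover = rng.choice(cover_idx, size=n_cover, replace=False)
    n_contam = int(round(scene_cfg.contamination_rate * n_cover))
    n_contam = min(n_contam, off_idx.size)
    displaced = set(rng.choice(np.arange(n_cover), size=n_contam,
                               replace=False).tolist()) if n_contam else set()
    off_targets = rng.choice(off_idx, size=n_contam, replace=False) if n_contam else []
    j = 0
    for i, flat in enumerate(chosen_cover):
        contaminated = i in displaced
        if contaminated:
            flat = off_targets[j]
            j += 1
        r, c = divmod(int(flat), spec.n_cols)
        x, y = spec.xy(r, c)
        rows.append(dict(x=x, y=y, year=year, label="cover",
                         contaminated=contaminated))
    for flat in rng.choice(none_idx, size=n_none, replace=False):
        r, c = divmod(int(flat), spec.n_cols)
        x, y = spec.xy(r, c)
        rows.append(dict(x=x, y=y, year=year, label="none", contaminated=False))
    return pd.DataFrame(rows)


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Generate a full co-registered scene; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    spec = config.grid
    codes = np.array(sorted(config.crop_codes), dtype=np.int32)
    k = codes.size

    cultivated = (rng.random(spec.shape) < config.cultivated_fraction).astype(np.int8)
    n_cult = int(cultivated.sum())
    if n_cult == 0:
        raise DegenerateSceneError("scene has zero cultivated pixels")

    # Crop rasters: uniform start, then Markov rotation per pixel.
    crop_rasters: dict[int, np.ndarray] = {}
    state = rng.integers(0, k, size=spec.shape)
    order = {y: i for i, y in enumerate(config.years)}
    cum = np.cumsum(config.rotation_matrix, axis=1)
    for year in config.years:
        if order[year] > 0:
            u = rng.random(spec.shape)
            state = (u[..., None] > cum[state]).sum(axis=-1)
        raster = codes[state].copy()
        raster[cultivated == 0] = INT_NODATA
        crop_rasters[year] = raster

    zones, polys = _county_zones(spec, config.n_counties)

    cc_truth: dict[int, np.ndarray] = {}
    red: dict[int, np.ndarray] = {}
    nir: dict[int, np.ndarray] = {}
    points = []
    ndvi_p = config.ndvi_params
    for year in config.years:
        rate = np.zeros(spec.shape)
        for code in codes:
            rate[crop_rasters[year] == code] = config.adoption_rate_for(int(code))
        truth = ((rng.random(spec.shape) < rate) & (cultivated == 1)).astype(np.int8)
        cc_truth[year] = truth

        ndvi = np.empty(spec.shape)
        covered = truth == 1
        ndvi[covered] = _truncnorm_draw(
            rng, ndvi_p.cover_mean, ndvi_p.cover_sd, int(covered.sum()))
        ndvi[~covered] = _truncnorm_draw(
            rng, ndvi_p.bare_mean, ndvi_p.bare_sd, int((~covered).sum()))
        red[year], nir[year] = _reflectance_from_ndvi(rng, ndvi)

        points.append(_sample_truth_points(rng, config, spec, cultivated,
                                           truth, year))

    scene = SyntheticScene(
        config=config, grid=spec, crop_rasters=crop_rasters,
        cultivated_mask=cultivated, cc_truth=cc_truth, red=red, nir=nir,
        county_zones=zones, county_polygons=polys,
        truth_points=pd.concat(points, ignore_index=True),
    )
    scene.nrcs_ledger = generate_nrcs_ledger(
        scene, config.subsidized_fraction, seed=config.seed + 1)
    return scene


def generate_nrcs_ledger(scene: SyntheticScene, subsidized_fraction: float,
                         seed: int, noise_sd: float = 0.02) -> pd.DataFrame:
    """Per county-year government-subsidized acres.

    Acres equal ``subsidized_fraction`` of true covered acres with mild
    multiplicative sampling noise, clipped so they never exceed truth.
    """
    if not 0.0 <= subsidized_fraction <= 1.0:
        raise ConfigurationError("subsidized_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for year in scene.years:
        truth = scene.true_cover_acres_by_county(year)
        for _, row in truth.iterrows():
            gov = subsidized_fraction * row["acres"]
            if noise_sd > 0 and gov > 0:
                gov *= 1.0 + rng.normal(0.0, noise_sd)
            gov = min(max(gov, 0.0), row["acres"])
            rows.append(dict(county_id=int(row["county_id"]), year=int(year),
                             government_acres=gov))
    return pd.DataFrame(rows)
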