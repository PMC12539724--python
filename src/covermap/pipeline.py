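"""End-to-end orchestration with file-based stage boundaries.

Every stage reads its inputs from and writes its outputs to the run
output directory, so any stage can be re-run standalone from a previous
stage's files.  A manifest (JSON) records a SHA-256 checksum for every
artifact, making reruns verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import adoption as adoption_mod
from . import cover_detect, landcover, sequences, soc_model
from .errors import CovermapError
from .grids import INT_NODATA, GridSpec, read_ascii_grid, write_ascii_grid
from .synthetic_scene import NDVIParams, SceneConfig, SyntheticScene, generate_scene

log = logging.getLogger(__name__)

STAGES = ("simulate", "classify", "sequences", "adoption", "soc")


@dataclass
class RunConfig:
    scene: SceneConfig = field(default_factory=SceneConfig)
    consolidation: str = "seven_class"
    reclass_csv: str | None = None
    ndvi_threshold: float = 0.3
    split_fraction: float = 0.7
    model_spec: str = "random_forest"
    top_k: int | None = 15
    min_acres: float = 0.0
    soc_params: soc_model.SOCParams = field(default_factory=soc_model.SOCParams)
    output_dir: str = "covermap_run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        scene_raw = dict(raw.get("scene", {}))
        if "years" in scene_raw:
            scene_raw["years"] = tuple(scene_raw["years"])
        if "ndvi_params" in scene_raw:
            scene_raw["ndvi_params"] = NDVIParams(**scene_raw["ndvi_params"])
        if "crop_codes" in scene_raw:
            scene_raw["crop_codes"] = {int(k): v for k, v
                                       in scene_raw["crop_codes"].items()}
        cfg = cls(scene=SceneConfig(**scene_raw))
        for key in ("consolidation", "reclass_csv", "ndvi_threshold",
                    "split_fraction", "model_spec", "top_k", "min_acres",
                    "output_dir", "seed"):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "soc_params" in raw:
            cfg.soc_params = soc_model.SOCParams(**raw["soc_params"])
        cfg.scene.seed = cfg.seed if "seed" in raw else cfg.scene.seed
        return cfg

    def reclass_map(self) -> landcover.ReclassMap:
        if self.reclass_csv:
            return landcover.ReclassMap.from_csv(self.reclass_csv,
                                                 self.consolidation)
        return landcover.ReclassMap(
            code_to_class=dict(self.scene.crop_codes),
            consolidation=self.consolidation)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class Manifest:
    """Stage-tagged artifact registry with checksums."""

    def __init__(self, root: Path, seed: int):
        self.root = Path(root)
        self.entries: dict[str, dict[str, str]] = {}
        self.seed = seed

    def add(self, stage: str, path: Path) -> None:
        rel = str(Path(path).relative_to(self.root))
        self.entries.setdefault(stage, {})[rel] = _sha256(Path(path))

    def write(self) -> Path:
        out = self.root / "manifest.json"
        out.write_text(json.dumps(
            {"seed": self.seed, "stages": self.entries}, indent=2,
            sort_keys=True))
        return out


# ---------------------------------------------------------------- simulate

def stage_simulate(cfg: RunConfig, manifest: Manifest) -> SyntheticScene:
    scene = generate_scene(cfg.scene)
    out = manifest.root / "scene"
    out.mkdir(parents=True, exist_ok=True)
    spec = scene.grid
    write_ascii_grid(out / "cultivated_mask.asc",
                     scene.cultivated_mask.astype(np.int32), spec)
    write_ascii_grid(out / "county_zones.asc", scene.county_zones, spec)
    for year in scene.years:
        write_ascii_grid(out / f"crop_{year}.asc", scene.crop_rasters[year], spec)
        write_ascii_grid(out / f"cc_truth_{year}.asc",
                         scene.cc_truth[year].astype(np.int32), spec)
        write_ascii_grid(out / f"red_{year}.asc", scene.red[year], spec)
        write_ascii_grid(out / f"nir_{year}.asc", scene.nir[year], spec)
    scene.truth_points.to_csv(out / "truth_points.csv", index=False)
    scene.nrcs_ledger.to_csv(out / "nrcs_ledger.csv", index=False)
    features = {"type": "FeatureCollection", "features": [
        {"type": "Feature", "properties": {"county_id": cid},
         "geometry": poly.__geo_interface__}
        for cid, poly in scene.county_polygons.items()]}
    (out / "counties.geojson").write_text(json.dumps(features))
    meta = {"years": list(scene.years), "seed": cfg.scene.seed}
    (out / "scene.json").write_text(json.dumps(meta, indent=2))
    for p in sorted(out.iterdir()):
        manifest.add("simulate", p)
    log.info("simulate: %d years on a %dx%d grid", len(scene.years),
             spec.n_rows, spec.n_cols)
    return scene


def _scene_years(root: Path) -> list[int]:
    return json.loads((root / "scene" / "scene.json").read_text())["years"]


# ---------------------------------------------------------------- classify

def stage_classify(cfg: RunConfig, manifest: Manifest) -> None:
    root = manifest.root
    scene_dir = root / "scene"
    out = root / "classify"
    out.mkdir(parents=True, exist_ok=True)
    mask, spec, _ = read_ascii_grid(scene_dir / "cultivated_mask.asc",
                                    dtype=np.int32)
    points = pd.read_csv(scene_dir / "truth_points.csv")
    for year in _scene_years(root):
        red, _, _ = read_ascii_grid(scene_dir / f"red_{year}.asc")
        nir, _, _ = read_ascii_grid(scene_dir / f"nir_{year}.asc")
        features = {"ndvi": landcover.compute_ndvi(red, nir),
                    "red": red, "nir": nir}
        pts = points[points["year"] == year]
        training = cover_detect.filter_training_points(
            pts, features, spec, threshold=cfg.ndvi_threshold)
        training = cover_detect.split_train_validation(
            training, fraction=cfg.split_fraction, seed=cfg.seed)
        cover = cover_detect.train_and_classify(
            training, features, mask, spec, model_spec=cfg.model_spec,
            seed=cfg.seed, year=year)
        write_ascii_grid(out / f"cover_{year}.asc", cover.grid, spec)
        cover.accuracy_report.to_csv(out / f"accuracy_{year}.csv", index=False)
        log.info("classify %d: dropped %d points, accuracy %.3f", year,
                 training.dropped_cover_points, cover.overall_accuracy)
    for p in sorted(out.iterdir()):
        manifest.add("classify", p)


# --------------------------------------------------------------- sequences

def stage_sequences(cfg: RunConfig, manifest: Manifest) -> None:
    root = manifest.root
    out = root / "sequences"
    out.mkdir(parents=True, exist_ok=True)
    years = _scene_years(root)
    reclass = cfg.reclass_map()
    class_rasters = {}
    cover_rasters = {}
    spec = None
    for year in years:
        crop, spec, _ = read_ascii_grid(root / "scene" / f"crop_{year}.asc",
                                        dtype=np.int32)
        class_rasters[year] = landcover.reclassify(crop, reclass, year=year)
        cover, _, _ = read_ascii_grid(root / "classify" / f"cover_{year}.asc",
                                      dtype=np.int32)
        cover_rasters[year] = cover
    report = sequences.rotation_report(years, class_rasters, cover_rasters,
                                       spec.pixel_acres)
    for name, per_year in report.items():
        if cfg.min_acres > 0:
            per_year = {y: t.suppress(cfg.min_acres)
                        for y, t in per_year.items()}
        tidy = sequences.tidy_tables(per_year)
        tidy.to_csv(out / f"{name}.csv", index=False)
        if cfg.top_k:
            top = sequences.tidy_tables(
                {y: sequences.PatternTable(t.top(cfg.top_k), t.total_pixels,
                                           t.total_acres)
                 for y, t in per_year.items()})
            top.to_csv(out / f"{name}_top{cfg.top_k}.csv", index=False)
    for p in sorted(out.iterdir()):
        manifest.add("sequences", p)


# ---------------------------------------------------------------- adoption

def stage_adoption(cfg: RunConfig, manifest: Manifest) -> None:
    root = manifest.root
    out = root / "adoption"
    out.mkdir(parents=True, exist_ok=True)
    zones, spec, _ = read_ascii_grid(root / "scene" / "county_zones.asc",
                                     dtype=np.int32)
    totals = []
    for year in _scene_years(root):
        cover, _, _ = read_ascii_grid(root / "classify" / f"cover_{year}.asc",
                                      dtype=np.int32)
        totals.append(adoption_mod.zonal_cover_acres(cover, zones,
                                                     spec.pixel_acres, year))
    total = pd.concat(totals, ignore_index=True)
    government = pd.read_csv(root / "scene" / "nrcs_ledger.csv")
    ledger = adoption_mod.compute_voluntary(total, government)
    ledger.to_csv(out / "county_ledger.csv", index=False)
    trends = adoption_mod.adoption_trends(ledger)
    trends.yearly.to_csv(out / "yearly_totals.csv", index=False)
    r, p_val, n = adoption_mod.funding_correlation(ledger)
    summary = pd.DataFrame([dict(
        first_year=trends.first_year, last_year=trends.last_year,
        voluntary_change_acres=trends.voluntary_change_acres,
        voluntary_change_pct=trends.voluntary_change_pct,
        cumulative_government_acre_years=trends.cumulative_government_acre_years,
        cumulative_voluntary_acre_years=trends.cumulative_voluntary_acre_years,
        cumulative_total_acre_years=trends.cumulative_total_acre_years,
        pearson_r=r, pearson_p=p_val, n=n)])
    summary.to_csv(out / "summary.csv", index=False)
    for p in sorted(out.iterdir()):
        manifest.add("adoption", p)


# --------------------------------------------------------------------- soc

def stage_soc(cfg: RunConfig, manifest: Manifest,
              acreage_csv: str | None = None) -> None:
    root = manifest.root
    out = root / "soc"
    out.mkdir(parents=True, exist_ok=True)
    if acreage_csv is not None:
        acreage = pd.read_csv(acreage_csv)
        if ("voluntary_acres" not in acreage.columns
                and {"total_acres", "government_acres"} <= set(acreage.columns)):
            acreage = adoption_mod.compute_voluntary(
                acreage[["year", "total_acres"]],
                acreage[["year", "government_acres"]])
    else:
        ledger = pd.read_csv(root / "adoption" / "county_ledger.csv")
        acreage = ledger.groupby("year", as_index=False)[
            ["government_acres", "voluntary_acres", "total_acres"]].sum()
    table = soc_model.soc_table(acreage, cfg.soc_params)
    table.to_csv(out / "soc_table.csv", index=False)
    soc_model.literature_rates().to_csv(out / "literature_rates.csv",
                                        index=False)
    rates = pd.DataFrame([dict(
        rate_tons_per_acre=soc_model.soc_rate(cfg.soc_params),
        rate_mg_per_ha=soc_model.convert_rate(
            soc_model.soc_rate(cfg.soc_params)))])
    rates.to_csv(out / "rate.csv", index=False)
    for p in sorted(out.iterdir()):
        manifest.add("soc", p)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "classify": stage_classify,
    "sequences": stage_sequences,
    "adoption": stage_adoption,
    "soc": stage_soc,
}


def run_pipeline(cfg: RunConfig, stages=STAGES,
                 acreage_csv: str | None = None) -> Path:
    """Run the requested stages; returns the manifest path.

    A stage failure aborts the run with a stage-tagged error after
    writing the partial manifest.
    """
    root = Path(cfg.output_dir)
    root.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(root, cfg.seed)
    for stage in stages:
        func = _STAGE_FUNCS[stage]
        try:
            if stage == "soc":
                func(cfg, manifest, acreage_csv=acreage_csv)
            else:
                func(cfg, manifest)
        except Exception as exc:
            manifest.write()
            raise CovermapError(f"[stage:{stage}] {exc}") from exc
    return manifest.write()
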