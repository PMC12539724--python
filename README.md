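# covermap

Winter cover-crop mapping and accounting on categorical rasters:

- **synthetic_scene** — co-registered multi-year CDL-style crop rasters with
  Markov rotation structure, winter red/NIR reflectance whose NDVI separates
  cover-cropped from bare pixels, ground-truth points with a configurable
  fraction of mislocated (farmstead) points, county zones, and a county-year
  subsidized-acreage ledger. Deterministic per seed.
- **landcover** — reclassification of integer crop codes into seven analysis
  classes (or a consolidated four-class legend), NDVI, cultivated masking.
- **cover_detect** — NDVI-threshold purification of cover-labeled training
  points (strictly greater than 0.3 by default), stratified 70/30
  train/validation split, and a pluggable binary classifier (random forest by
  default; a pure NDVI-threshold classifier is provided as an exact oracle),
  plus a winter-wheat-for-grain share report.
- **sequences** — pixel-wise combine (cross-tabulation) of 2–3 categorical
  layers, pattern enumeration (7×2 = 14, 7×2×7 = 98, 133×2×133 = 35,378),
  and per-year crop→cover, cover→crop, crop→cover→crop pattern tables with
  acreage and percent-of-cropland accounting.
- **adoption** — county zonal acreage, the exact voluntary = total −
  government decomposition (negatives flagged, never clamped), first-to-last
  year trends, cumulative acre-years, and Pearson correlation between funding
  sources.
- **soc_model** — biomass-chain soil-organic-carbon model: with the default
  constants (AG = 3500 lbs/acre, BG = 1747 lbs/acre, P = 0.30, Conc = 0.50,
  E = 0.50) the sequestration rate is 0.524625 ≈ 0.52 tons C/acre/year;
  per-year SOC tables by funding source, tons/acre ↔ Mg/ha conversion, and a
  table of published literature rates.

Rasters are held as numpy arrays sharing one `GridSpec` and persisted as
ESRI ASCII grids (plain text); points and ledgers are CSV; county zones are
also emitted as GeoJSON. A 2013–2019 regional acreage ledger ships as
package data (`covermap.datasets.regional_cca_ledger`).

## CLI

```sh
covermap all --config run.yaml --seed 1 --output-dir out/
```

Subcommands `simulate`, `classify`, `sequences`, `adoption`, `soc` each
restart from the files a previous stage left in the output directory, so any
stage can be re-run standalone. `covermap soc --acreage-csv acres.csv` runs
the carbon model directly on a yearly acreage table. Every run writes a
`manifest.json` with SHA-256 checksums of all artifacts; reruns with the
same config and seed are bit-identical.

Minimal `run.yaml`:

```yaml
scene:
  n_rows: 120
  n_cols: 120
  years: [2013, 2014, 2015]
  n_counties: 4
  cc_adoption_rate: 0.3
seed: 1
model_spec: random_forest
output_dir: out
```

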