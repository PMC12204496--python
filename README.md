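# isletmap

Semi-automated single-islet histopathology analysis of pancreatic tissue
sections: islet object construction from multiplexed stain masks, hormone
area quantification, immune-cell burden and insulitis calling, single-islet
clustering, and boundary-aware spatial statistics — driven by a synthetic
cohort generator so the whole pipeline is testable offline.

## Modules

| Module | Role |
| --- | --- |
| `isletmap.synth` | Synthetic tissue polygons, islet tables with ground-truth labels, rendered stain masks, cell point sets; stage templates ship as editable JSON presets (`src/isletmap/templates/`). |
| `isletmap.segmentation` | Islet objects from the union of six defining stains: hole filling, 1,000 µm² minimum size, 10 µm border margin, shape descriptors (circularity, solidity, aspect ratio), equivalent diameter/volume, cell density. |
| `isletmap.hormones` | Per-islet staining-area fractions for 9 channels, endocrine union, pairwise Jaccard indices (56 ordered pairs), 1% subset rules (IDI, GCG-deficient, PPY/SST-positive), section summaries, mass estimates, 14-bin exponential size-property fits. |
| `isletmap.immune` | Non-overlapping 20 µm peri-islet regions (watershed split), CD45 attribution, burden metrics, consensus insulitis call (≥15 CD45 on ≥3 islets per donor). |
| `isletmap.clustering` | z-scored log-area feature matrix, UMAP (50 / 0.1 / 1000), two-round DBSCAN (0.5/50 then 0.2/20), semantic label mapping to clusters I–V-BC, deterministic rule-based fallback key, cluster magnitude tables with `<3 islets`/`<2 donors` suppression. |
| `isletmap.spatial` | Boundary-weighted modified Ripley's K (K = 1 under spatial randomness), fractal dimension, Delaunay neighbourhood metrics with 4,000 µm pruning and the 4 mm fallback, cluster-scoped 8 mm Delaunay with isolated-islet fractions, GeoJSON back-projection maps. |
| `isletmap.pipeline` / `isletmap.io` / `isletmap.cli` | End-to-end orchestration, CSV/GeoJSON/PNG formats, configuration, manifest, cohort report. |

All coordinates are physical micrometres, origin at the tissue bounding-box
corner, y-axis down (raster convention). Islet tables are CSV with a
`polygon_wkt` column; tissue boundaries are GeoJSON polygons.

## CLI

```bash
isletmap synth   --template Ctrl_PT --seed 1 --out out/           # synthetic section
isletmap segment --masks out/masks --tissue out/tissue.geojson --out islets.csv
isletmap quantify --islets islets.csv --tissue out/tissue.geojson --out q.csv
isletmap immune  --islets q.csv --cells out/cells.csv --tissue out/tissue.geojson --out imm.csv
isletmap cluster --islets imm.csv --seed 1 --method umap --out clustered.csv
isletmap spatial --islets clustered.csv --tissue out/tissue.geojson --out spatial/
isletmap run     --seed 1 --out cohort/                           # all-in-one synthetic cohort
```

Built-in templates: `{Ctrl,AAb,T1DS,T1DL}_{PT,PH}`; pass a JSON path to use
an edited template. `isletmap run` accepts `--config config.json`
(see `isletmap.pipeline.PipelineConfig`; exit codes 0/1/2 =
ok/validation/runtime).

## Notes

- Determinism: every random draw descends from an explicit seed; two runs
  with the same config and seed give byte-identical outputs (UMAP included,
  via its `random_state`).
- The donor-level jitter default (`StageTemplate.donor_jitter = 0.1`) is a
  guess: source summaries report group-level statistics only.
- Stain masks are written as PNG + JSON sidecar (pixel size in µm/px);
  binary rasters are derived artifacts and are always regenerable from the
  islet tables.
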