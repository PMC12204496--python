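"""End-to-end orchestration of the analysis stages over a synthetic cohort.

Stage order: generate (or load) → [optional raster round-trip: render +
re-segment] → hormone subsets → immune (peri regions, attribution,
insulitis) → slide Delaunay → Ripley/fractal → clustering → cluster-scope
Delaunay → cohort report.  Identical config + seed give identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from . import __version__
from .clustering import (
    assemble_features,
    cluster_summaries,
    cluster_two_round,
    embed_umap,
    map_cluster_labels,
    rule_based_key,
)
from .core import CHANNELS_9, TissueSection
from .hormones import HormoneProfile, classify_subsets, estimate_mass, section_summaries
from .immune import attribute_cells, burden_metrics, call_insulitis, expand_peri_regions
from .io import write_islet_table, write_tissue_geojson
from .spatial import (
    DEFAULT_RADII_UM,
    cluster_delaunay,
    delaunay_metrics,
    fractal_dimension,
    ripley_modified,
)
from .synth import StageTemplate, generate_cells, generate_islets, generate_tissue, load_template

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All numeric defaults equal the study's printed values."""

    master_seed: int = 0
    # cohort layout
    donors_per_group: int = 2
    regions: tuple[str, ...] = ("PT",)
    tissue_width_mm: float = 8.0
    tissue_height_mm: float = 8.0
    tissue_irregularity: float = 0.2
    # stage parameters
    min_islet_area_um2: float = 1000.0
    border_margin_um: float = 10.0
    peri_margin_um: float = 20.0
    subset_threshold: float = 0.01
    insulitis_cd45_per_islet: int = 15
    insulitis_min_islets: int = 3
    delaunay_max_radius_um: float = 4000.0
    cluster_delaunay_radius_um: float = 8000.0
    ripley_radii_um: tuple[float, ...] = tuple(DEFAULT_RADII_UM)
    umap_n_neighbors: int = 50
    umap_min_dist: float = 0.1
    umap_n_epochs: int = 1000
    dbscan_major: tuple[float, int] = (0.5, 50)
    dbscan_sub: tuple[float, int] = (0.2, 20)
    # toggles
    cluster_method: str = "umap"  # "umap" | "rule"
    raster_route: bool = False
    raster_pixel_size_um: float = 2.0
    run_ripley: bool = True

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        for key in ("regions", "ripley_radii_um", "dbscan_major", "dbscan_sub"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _section_seed(master_seed: int, stage: str, region: str, donor_idx: int) -> int:
    h = hashlib.sha256(f"{master_seed}:{stage}:{region}:{donor_idx}".encode())
    return int.from_bytes(h.digest()[:8], "big") % (2**31)


def run_section(
    template: StageTemplate,
    tissue: TissueSection,
    seed: int,
    config: PipelineConfig,
) -> dict:
    """Run all per-section stages; returns tables and summaries."""
    islets, truth = generate_islets(template, tissue, seed)
    cells, cell_truth = generate_cells(
        islets, truth, template, seed + 1, peri_margin_um=config.peri_margin_um
    )

    if config.raster_route and len(islets):
        islets = _raster_roundtrip(islets, truth, tissue, config)

    # subset classification from the measured fractions
    flags = []
    for _, row in islets.iterrows():
        profile = HormoneProfile(
            islet_id=int(row["islet_id"]),
            fraction_of_islet={ch: float(row[f"frac_{ch}"]) for ch in CHANNELS_9},
        )
        flags.append(classify_subsets(profile, threshold=config.subset_threshold))
    islets["is_IDI"] = [f.is_IDI for f in flags]
    islets["is_GCG_deficient"] = [f.is_GCG_deficient for f in flags]
    islets["is_PPY_positive"] = [f.is_PPY_positive for f in flags]
    islets["is_SST_positive"] = [f.is_SST_positive for f in flags]

    # immune stage
    islet_objects = _islet_objects(islets)
    peri = expand_peri_regions(islet_objects, tissue, margin_um=config.peri_margin_um)
    records, n_unattributed = attribute_cells(islet_objects, peri, cells)
    ins_flags, _donor_positive_here = call_insulitis(
        records,
        islet_threshold=config.insulitis_cd45_per_islet,
        donor_threshold=config.insulitis_min_islets,
    )
    records["insulitic"] = ins_flags
    islets = islets.merge(
        records.drop(columns=["zero_nuclei_flag"]), on="islet_id", how="left"
    )

    # slide-wide Delaunay + Ripley
    centroids = islets[["centroid_x_um", "centroid_y_um"]].to_numpy(float)
    if len(islets):
        dl = delaunay_metrics(
            centroids,
            islet_ids=islets["islet_id"].to_numpy(),
            max_radius_um=config.delaunay_max_radius_um,
        )
        islets = islets.merge(dl, on="islet_id", how="left")
    ripley = None
    fdim = None
    if config.run_ripley and len(islets) >= 2:
        radii = np.asarray(config.ripley_radii_um, float)
        max_r = 0.45 * min(
            tissue.boundary.bounds[2] - tissue.boundary.bounds[0],
            tissue.boundary.bounds[3] - tissue.boundary.bounds[1],
        )
        radii = radii[radii <= max(max_r, radii[0])]
        ripley = ripley_modified(centroids, tissue.boundary, radii)
        try:
            fdim = fractal_dimension(ripley.radii_um, ripley.mean_adjusted_counts)
        except ValueError:
            fdim = None

    summary = section_summaries(islets, tissue)
    summary["n_unattributed_cells"] = n_unattributed
    summary["ripley_auc"] = ripley.auc if ripley is not None else None
    summary["fractal_dimension"] = fdim
    return {
        "islets": islets,
        "truth": truth,
        "cells": cells,
        "cell_truth": cell_truth,
        "records": records,
        "summary": summary,
        "tissue": tissue,
        "template": template,
        "ripley": ripley,
    }


def _islet_objects(islets: pd.DataFrame):
    from .core import IsletObject

    out = []
    for _, row in islets.iterrows():
        out.append(
            IsletObject(
                id=int(row["islet_id"]),
                polygon=shapely.from_wkt(row["polygon_wkt"]),
                nuclei_count=int(row["nuclei_count"]),
                cell_density_per_mm2=float(row["cell_density_per_mm2"]),
            )
        )
    return out


def _raster_roundtrip(islets, truth, tissue, config):
    """Render stain masks and re-derive geometry + fractions from pixels."""
    from .hormones import hormone_fractions
    from .segmentation import build_islets
    from .synth import render_stain_masks

    masks = render_stain_masks(islets, config.raster_pixel_size_um)
    objs = build_islets(
        {k: masks[k] for k in masks},
        tissue,
        min_islet_area_um2=config.min_islet_area_um2,
        border_margin_um=config.border_margin_um,
    )
    rows = []
    gen_xy = islets[["centroid_x_um", "centroid_y_um"]].to_numpy(float)
    for obj in objs:
        d = np.hypot(gen_xy[:, 0] - obj.centroid[0], gen_xy[:, 1] - obj.centroid[1])
        src = islets.iloc[int(np.argmin(d))]
        profile = hormone_fractions(obj, masks)
        row = {
            "islet_id": int(src["islet_id"]),
            "donor_id": src["donor_id"],
            "region": src["region"],
            "stage": src["stage"],
            "centroid_x_um": obj.centroid[0],
            "centroid_y_um": obj.centroid[1],
            "area_um2": obj.area_um2,
            "perimeter_um": obj.perimeter_um,
            "circularity": obj.circularity,
            "solidity": obj.solidity,
            "aspect_ratio": obj.aspect_ratio,
            "equivalent_diameter_um": obj.equivalent_diameter_um,
            "nuclei_count": int(src["nuclei_count"]),
            "cell_density_per_mm2": float(src["cell_density_per_mm2"]),
            "frac_endocrine": profile.fraction_of_islet["endocrine_union"],
            "polygon_wkt": obj.polygon.wkt,
        }
        for ch in CHANNELS_9:
            row[f"frac_{ch}"] = profile.fraction_of_islet[ch]
        rows.append(row)
    return pd.DataFrame(rows, columns=list(islets.columns))


def run_pipeline(config: PipelineConfig, out_dir=None, templates=None) -> dict:
    """Run the full synthetic cohort and assemble the cohort report.

    ``templates`` maps (stage, region) to StageTemplate; built-in presets
    are used when omitted.  Artifacts (CSV/GeoJSON/JSON) are written when
    ``out_dir`` is given.
    """
    if templates is None:
        templates = {}
        for region in config.regions:
            for stage in ("Ctrl", "AAb", "T1DS", "T1DL"):
                templates[(stage, region)] = load_template(f"{stage}_{region}")

    sections = []
    counters = {}
    for (stage, region), template in sorted(templates.items()):
        for d in range(config.donors_per_group):
            donor_id = f"{stage}-{d + 1:02d}"
            seed = _section_seed(config.master_seed, stage, region, d)
            rng = np.random.default_rng(seed)
            donor_template = template.with_donor_jitter(rng)
            tissue = generate_tissue(
                seed,
                config.tissue_width_mm,
                config.tissue_height_mm,
                config.tissue_irregularity,
                region=region,
                donor_id=donor_id,
                stage=stage,
                pancreas_region_weight_g=template.pancreas_region_weight_g,
            )
            result = run_section(donor_template, tissue, seed, config)
            result["donor_id"] = donor_id
            sections.append(result)
            counters[f"{donor_id}:{region}:islets"] = len(result["islets"])
    pooled = pd.concat(
        [s["islets"] for s in sections], ignore_index=True
    )
    pooled["section_idx"] = np.repeat(
        np.arange(len(sections)), [len(s["islets"]) for s in sections]
    )

    # clustering over the pooled islet set
    if config.cluster_method == "umap" and len(pooled) >= config.umap_n_neighbors + 1:
        features = assemble_features(pooled)
        embedding = embed_umap(
            features,
            n_neighbors=config.umap_n_neighbors,
            min_dist=config.umap_min_dist,
            n_epochs=config.umap_n_epochs,
            seed=config.master_seed,
        )
        assignments = cluster_two_round(embedding)
        labeled, mapping_report = map_cluster_labels(assignments, pooled)
        pooled["cluster"] = labeled["major_cluster"].to_numpy()
        pooled["subcluster"] = labeled["sub_id"].to_numpy()
        pooled["umap_x"] = embedding[:, 0]
        pooled["umap_y"] = embedding[:, 1]
    else:
        pooled["cluster"] = [
            rule_based_key(
                {
                    "ProINS_total": row["frac_ProINS_total"],
                    "INS": row["frac_INS"],
                    "GCG": row["frac_GCG"],
                    "PPY": row["frac_PPY"],
                },
                int(row["cd45_total"]),
                region=row["region"],
            )
            for _, row in pooled.iterrows()
        ]
        pooled["subcluster"] = ""
        mapping_report = {"method": "rule_based_key"}

    # cluster-scope Delaunay per section
    cluster_tables = []
    for idx, s in enumerate(sections):
        sel = pooled["section_idx"] == idx
        sub = pooled[sel]
        if len(sub) == 0:
            continue
        per_islet, per_cluster = cluster_delaunay(
            sub[["centroid_x_um", "centroid_y_um"]].to_numpy(float),
            sub["cluster"].to_numpy(),
            islet_ids=sub["islet_id"].to_numpy(),
            max_radius_um=config.cluster_delaunay_radius_um,
        )
        per_cluster.insert(0, "donor_id", s["donor_id"])
        per_cluster.insert(1, "region", s["tissue"].region)
        cluster_tables.append(per_cluster)
        iso = dict(
            zip(
                per_islet["islet_id"],
                per_islet["is_isolated"],
            )
        )
        pooled.loc[sel, "is_isolated"] = sub["islet_id"].map(iso).to_numpy()
    cluster_delaunay_table = (
        pd.concat(cluster_tables, ignore_index=True)
        if cluster_tables
        else pd.DataFrame()
    )

    report = build_cohort_report(pooled, sections, config)
    magnitudes = cluster_summaries(pooled)

    manifest = {
        "isletmap_version": __version__,
        "config_hash": config.config_hash,
        "config": json.loads(config.to_json()),
        "stage_counters": counters,
        "n_islets_total": int(len(pooled)),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_islet_table(pooled, out_dir / "islets.csv")
        for idx, s in enumerate(sections):
            tag = f"{s['donor_id']}_{s['tissue'].region}"
            write_tissue_geojson(s["tissue"], out_dir / f"tissue_{tag}.geojson")
            s["cells"].to_csv(out_dir / f"cells_{tag}.csv", index=False)
        if len(cluster_delaunay_table):
            cluster_delaunay_table.to_csv(
                out_dir / "cluster_delaunay.csv", index=False
            )
        magnitudes.to_csv(out_dir / "cluster_magnitudes.csv", index=False)
        (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        (out_dir / "diagnosis.json").write_text(
            json.dumps(report["insulitis_diagnosis"], indent=1, sort_keys=True)
        )
    return {
        "islets": pooled,
        "sections": sections,
        "report": report,
        "cluster_magnitudes": magnitudes,
        "cluster_delaunay": cluster_delaunay_table,
        "mapping_report": mapping_report,
        "manifest": manifest,
    }


def build_cohort_report(pooled: pd.DataFrame, sections: list[dict], config: PipelineConfig) -> dict:
    """Per donor-region summary block plus donor-level insulitis calls."""
    report: dict = {"donor_regions": {}, "insulitis_diagnosis": {}}
    # donor-level insulitis pools all of a donor's sections (PT and PH)
    for donor_id, grp in pooled.groupby("donor_id", observed=True):
        n_insulitic = int((grp["cd45_total"] >= config.insulitis_cd45_per_islet).sum())
        report["insulitis_diagnosis"][str(donor_id)] = {
            "n_insulitic_islets": n_insulitic,
            "positive": n_insulitic >= config.insulitis_min_islets,
        }
    for s in sections:
        islets = s["islets"]
        tissue = s["tissue"]
        key = f"{s['donor_id']}:{tissue.region}"
        sel = pooled[
            (pooled["donor_id"] == s["donor_id"]) & (pooled["region"] == tissue.region)
        ]
        block = dict(s["summary"])
        rel_islet = block["relative_islet_area_pct"] / 100.0
        block["islet_mass_mg"] = estimate_mass(
            rel_islet, tissue.pancreas_region_weight_g
        )
        if len(islets):
            block["frac_IDI"] = float(islets["is_IDI"].mean())
            block["frac_GCG_deficient"] = float(islets["is_GCG_deficient"].mean())
            block["frac_PPY_positive"] = float(islets["is_PPY_positive"].mean())
            block["frac_SST_positive"] = float(islets["is_SST_positive"].mean())
            block.update(
                {
                    f"burden_{k}": v
                    for k, v in burden_metrics(s["records"], sel).items()
                    if not isinstance(v, dict)
                }
            )
            block["cluster_fractions"] = (
                sel["cluster"].value_counts(normalize=True).to_dict()
            )
        report["donor_regions"][key] = _jsonable(block)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, float) and np.isnan(obj):
        return None
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
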