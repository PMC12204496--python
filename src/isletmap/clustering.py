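"""Single-islet feature assembly, UMAP embedding, two-round DBSCAN
clustering, semantic cluster-label mapping, and the rule-based fallback key.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .core import HORMONES_8
from .hormones import SUBSET_THRESHOLD

#: UMAP / DBSCAN defaults.
UMAP_N_NEIGHBORS = 50
UMAP_MIN_DIST = 0.1
UMAP_N_EPOCHS = 1000
DBSCAN_MAJOR = (0.5, 50)  # (eps, min_samples) round 1
DBSCAN_SUB = (0.2, 20)  # round 2

#: Feature columns: log-transformed raw areas of the eight hormone
#: stains, the endocrine union, islet area and mean Delaunay area, plus
#: the raw CD45 count and circularity.
AREA_FEATURES = (
    [f"frac_{ch}" for ch in HORMONES_8]
    + ["frac_endocrine"]
)
REQUIRED_COLUMNS = (
    AREA_FEATURES + ["area_um2", "delaunay_mean_area_um2", "cd45_total", "circularity"]
)


class SchemaError(KeyError):
    """The islet table is missing a required column."""


def assemble_features(islets: pd.DataFrame) -> np.ndarray:
    """Build the z-scored single-islet feature matrix.

    Hormone fractions are converted to raw stained areas (µm²), log
    transformed as ln(x + 1) (pseudocount guards the common zero areas of
    insulin-deficient islets), pooled with log islet area, log mean
    Delaunay area, the raw CD45 count and circularity, then each column
    is standardized with the population SD.  Constant columns become
    zeros with a degenerate-variance warning.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in islets.columns]
    if missing:
        raise SchemaError(f"islet table missing column(s): {missing}")
    area = islets["area_um2"].to_numpy(float)
    cols = []
    for c in AREA_FEATURES:
        cols.append(np.log1p(islets[c].to_numpy(float) * area))
    cols.append(np.log1p(area))
    cols.append(np.log1p(islets["delaunay_mean_area_um2"].to_numpy(float)))
    cols.append(islets["cd45_total"].to_numpy(float))
    cols.append(islets["circularity"].to_numpy(float))
    mat = np.column_stack(cols)
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0)  # population SD
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} feature column(s) have zero variance"
        )
        sd = np.where(degenerate, 1.0, sd)
    z = (mat - mean) / sd
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite values in feature matrix")
    return z


def embed_umap(
    features: np.ndarray,
    n_neighbors: int = UMAP_N_NEIGHBORS,
    min_dist: float = UMAP_MIN_DIST,
    n_epochs: int = UMAP_N_EPOCHS,
    seed: int = 0,
) -> np.ndarray:
    """2-D UMAP embedding; deterministic for a fixed seed and library version."""
    if len(features) < n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1={n_neighbors + 1} islets for UMAP; "
            "use the rule-based key for small sets"
        )
    import umap  # deferred: numba compilation is slow

    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        n_epochs=n_epochs,
        random_state=int(seed),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.asarray(reducer.fit_transform(features), float)


def cluster_two_round(embedding: np.ndarray) -> pd.DataFrame:
    """Two-round DBSCAN on the embedding.

    Round 1 (eps 0.5, min 50 points) defines major clusters; round 2
    (eps 0.2, min 20 points) defines subclusters, nested into the major
    cluster holding the majority of their points.  Noise points get the
    major label -1 (reported downstream as "null").
    """
    embedding = np.asarray(embedding, float)
    major = DBSCAN(eps=DBSCAN_MAJOR[0], min_samples=DBSCAN_MAJOR[1]).fit_predict(
        embedding
    )
    sub = DBSCAN(eps=DBSCAN_SUB[0], min_samples=DBSCAN_SUB[1]).fit_predict(embedding)
    # nest subclusters by majority overlap with a major cluster
    sub_label = np.array(["" for _ in range(len(embedding))], dtype=object)
    for s in np.unique(sub):
        if s < 0:
            continue
        members = sub == s
        majors, counts = np.unique(major[members], return_counts=True)
        host = majors[np.argmax(counts)]
        sub_label[members] = f"{host}.{s}"
    return pd.DataFrame({"major_id": major, "sub_id": sub_label})


def rule_based_key(
    profile: dict[str, float],
    cd45_total: int,
    region: str = "PT",
    threshold: float = SUBSET_THRESHOLD,
) -> str:
    """Deterministic decision list approximating the cluster vocabulary
    from three-parameter stains (INS/ProINS, GCG, CD45; PPY optional).

    Truth table (fractions compared against the 1% threshold)::

        beta+ (ProINS or INS >= 1%):
            CD45 >= 1                      -> II
            GCG < 1% and PPY >= 1%         -> III   (PPY+ beta islets, PH)
            otherwise                      -> I
        beta-:
            PPY >= 1% and GCG < 1%         -> IV    (PPY-dominant)
            CD45 >= 1                      -> V-A
            otherwise                      -> V-BC
    """
    beta = (
        profile.get("ProINS_total", 0.0) >= threshold
        or profile.get("INS", 0.0) >= threshold
    )
    gcg = profile.get("GCG", 0.0) >= threshold
    ppy = profile.get("PPY", 0.0) >= threshold
    if beta:
        if cd45_total >= 1:
            return "II"
        if ppy and not gcg:
            return "III"
        return "I"
    if ppy and not gcg:
        return "IV"
    return "V-A" if cd45_total >= 1 else "V-BC"


def map_cluster_labels(
    assignments: pd.DataFrame,
    islets: pd.DataFrame,
    purity_threshold: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Map numeric DBSCAN ids to the semantic vocabulary {I..V-BC}.

    Each DBSCAN cluster is labeled by applying the rule-based key to its
    per-islet profiles and taking the majority vote; clusters whose
    majority label covers less than ``purity_threshold`` of members are
    reported as "unassigned" (never silently merged).  Noise points map
    to "null".  Returns (labeled assignments, mapping report).
    """
    labels = np.array(["null"] * len(assignments), dtype=object)
    report: dict = {"clusters": {}}
    per_islet_keys = np.array(
        [
            rule_based_key(
                {
                    "ProINS_total": row.get("frac_ProINS_total", 0.0),
                    "INS": row.get("frac_INS", 0.0),
                    "GCG": row.get("frac_GCG", 0.0),
                    "PPY": row.get("frac_PPY", 0.0),
                },
                int(row.get("cd45_total", 0)),
                region=row.get("region", "PT"),
            )
            for _, row in islets.iterrows()
        ],
        dtype=object,
    )
    major = assignments["major_id"].to_numpy()
    for m in np.unique(major):
        if m < 0:
            continue
        members = major == m
        keys, counts = np.unique(per_islet_keys[members], return_counts=True)
        best = int(np.argmax(counts))
        purity = counts[best] / members.sum()
        label = str(keys[best]) if purity >= purity_threshold else "unassigned"
        labels[members] = label
        report["clusters"][int(m)] = {
            "n": int(members.sum()),
            "label": label,
            "purity": float(purity),
        }
    out = assignments.copy()
    out["major_cluster"] = labels
    return out, report


def cluster_summaries(
    islets: pd.DataFrame,
    min_islets: int = 3,
    min_donors: int = 2,
) -> pd.DataFrame:
    """Relative cluster magnitudes per donor-region with suppression.

    Fractions are over all labeled + null islets of a donor-region (they
    sum to 1).  Any cluster cell backed by fewer than 3 islets, and any
    cluster represented by fewer than 2 donors within its stage-region
    group, is suppressed with a machine-readable reason.
    """
    req = {"donor_id", "region", "stage", "cluster"}
    missing = req - set(islets.columns)
    if missing:
        raise SchemaError(f"missing column(s): {sorted(missing)}")
    rows = []
    for (donor, region, stage), grp in islets.groupby(
        ["donor_id", "region", "stage"], observed=True
    ):
        total = len(grp)
        for cluster, sub in grp.groupby("cluster", observed=True):
            rows.append(
                {
                    "donor_id": donor,
                    "region": region,
                    "stage": stage,
                    "cluster": cluster,
                    "n_islets": len(sub),
                    "fraction": len(sub) / total,
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    # donor support per stage-region-cluster
    support = (
        table.groupby(["stage", "region", "cluster"], observed=True)["donor_id"]
        .nunique()
        .rename("n_donors")
        .reset_index()
    )
    table = table.merge(support, on=["stage", "region", "cluster"], how="left")
    reasons = []
    for _, row in table.iterrows():
        r = []
        if row["n_islets"] < min_islets:
            r.append("<3 islets")
        if row["n_donors"] < min_donors:
            r.append("<2 donors")
        reasons.append(";".join(r))
    table["suppressed"] = [bool(r) for r in reasons]
    table["suppression_reason"] = reasons
    return table
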