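"""Per-islet and per-section hormone staining quantification.

Covers staining-area fractions, pairwise overlap (Jaccard) statistics,
the 1% subset classification rules, endocrine mass estimates, and the
size-binned exponential property fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from skimage import draw

from .core import (
    CHANNELS_9,
    HORMONES_8,
    IsletObject,
    MissingChannelError,
    StainMask,
    TissueSection,
)

#: Number of equal-width log2 size bins used for the size-stratified fits.
DEFAULT_N_BINS = 14

#: Subset threshold: <1% staining area of islet area means "deficient".
SUBSET_THRESHOLD = 0.01


@dataclass
class HormoneProfile:
    islet_id: int
    fraction_of_islet: dict[str, float]

    def __post_init__(self) -> None:
        for k, v in self.fraction_of_islet.items():
            if not 0.0 <= v <= 1.0 + 1e-9:
                raise ValueError(f"fraction {k}={v} outside [0, 1]")


@dataclass
class SubsetFlags:
    islet_id: int
    is_IDI: bool
    is_GCG_deficient: bool
    is_PPY_positive: bool
    is_SST_positive: bool


def rasterize_polygon(polygon, shape: tuple[int, int], pixel_size_um: float) -> np.ndarray:
    """Boolean footprint of a polygon on the mask grid (pixel centres)."""
    coords = np.asarray(polygon.exterior.coords)
    rr, cc = draw.polygon(
        coords[:, 1] / pixel_size_um - 0.5, coords[:, 0] / pixel_size_um - 0.5, shape
    )
    out = np.zeros(shape, dtype=bool)
    out[rr, cc] = True
    return out


def hormone_fractions(
    islet: IsletObject, channel_masks: dict[str, StainMask]
) -> HormoneProfile:
    """Stained area inside the islet per channel, as a fraction of islet area.

    ``endocrine_union`` is the fraction covered by the union of the eight
    hormone stains.  A missing channel raises — no silent zeros.
    """
    missing = [c for c in CHANNELS_9 if c not in channel_masks]
    if missing:
        raise MissingChannelError(f"missing channel(s): {missing}")
    ref = channel_masks[CHANNELS_9[0]]
    footprint = rasterize_polygon(islet.polygon, ref.data.shape, ref.pixel_size_um)
    n_islet = int(footprint.sum())
    if n_islet == 0:
        raise ValueError("islet polygon rasterizes to zero pixels on this grid")
    fractions: dict[str, float] = {}
    union = np.zeros(ref.data.shape, dtype=bool)
    for ch in CHANNELS_9:
        m = channel_masks[ch]
        if not ref.same_grid(m):
            raise ValueError("channel masks are not co-registered")
        inside = m.data & footprint
        fractions[ch] = float(inside.sum()) / n_islet
        if ch in HORMONES_8:
            union |= inside
    fractions["endocrine_union"] = float(union.sum()) / n_islet
    return HormoneProfile(islet_id=islet.id, fraction_of_islet=fractions)


def jaccard_pairs(
    islet: IsletObject, channel_masks: dict[str, StainMask]
) -> pd.DataFrame:
    """All 56 ordered hormone-stain pairs with Jaccard index and
    double-positive fraction, computed on within-islet stained pixels.

    J = |A∩B| / |A∪B|, defined as 0 when the union is empty.
    """
    present = [c for c in HORMONES_8 if c in channel_masks]
    if len(present) < 2:
        raise ValueError("need at least two hormone channels")
    ref = channel_masks[present[0]]
    footprint = rasterize_polygon(islet.polygon, ref.data.shape, ref.pixel_size_um)
    n_islet = max(1, int(footprint.sum()))
    inside = {c: channel_masks[c].data & footprint for c in present}
    rows = []
    for a in present:
        for b in present:
            if a == b:
                continue
            inter = int((inside[a] & inside[b]).sum())
            uni = int((inside[a] | inside[b]).sum())
            rows.append(
                {
                    "islet_id": islet.id,
                    "channel_a": a,
                    "channel_b": b,
                    "jaccard": inter / uni if uni > 0 else 0.0,
                    "double_positive_fraction": inter / n_islet,
                }
            )
    return pd.DataFrame(rows)


def classify_subsets(
    profile: HormoneProfile, threshold: float = SUBSET_THRESHOLD
) -> SubsetFlags:
    """Apply the 1% staining-area rules.

    Deficiency is strict "<" (ProINS for IDIs, GCG for GCG-deficient);
    positivity is ">=" (PPY, SST).
    """
    f = profile.fraction_of_islet
    return SubsetFlags(
        islet_id=profile.islet_id,
        is_IDI=f["ProINS_total"] < threshold,
        is_GCG_deficient=f["GCG"] < threshold,
        is_PPY_positive=f["PPY"] >= threshold,
        is_SST_positive=f["SST"] >= threshold,
    )


def section_summaries(islets: pd.DataFrame, tissue: TissueSection) -> dict:
    """Per-section summary: cumulative stained areas, islet density,
    relative islet area, and the INS:GCG cumulative-area ratio.

    ``islets`` is the islet table with ``area_um2`` and ``frac_*`` columns.
    """
    area_mm2 = tissue.parenchymal_area_mm2
    if area_mm2 <= 0:
        raise ValueError("parenchymal area must be positive")
    out: dict = {
        "n_islets": int(len(islets)),
        "islet_density_per_mm2": len(islets) / area_mm2,
    }
    if len(islets) == 0:
        out["relative_islet_area_pct"] = 0.0
        out["ins_gcg_ratio"] = None
        out["ins_gcg_undefined"] = True
        for ch in CHANNELS_9 + ("endocrine_union",):
            out[f"cum_area_{ch}_um2"] = 0.0
        return out
    islet_area = float(islets["area_um2"].sum())
    out["relative_islet_area_pct"] = islet_area / (area_mm2 * 1e6) * 100.0
    for ch in CHANNELS_9 + ("endocrine_union",):
        col = f"frac_{ch}" if ch != "endocrine_union" else "frac_endocrine"
        out[f"cum_area_{ch}_um2"] = float(
            (islets["area_um2"] * islets[col]).sum()
        )
    ins = out["cum_area_INS_um2"]
    gcg = out["cum_area_GCG_um2"]
    out["ins_gcg_undefined"] = gcg == 0
    out["ins_gcg_ratio"] = None if gcg == 0 else ins / gcg
    return out


#: Sentinel for mass estimates that cannot be computed (weight unknown).
MASS_MISSING = float("nan")


def estimate_mass(relative_fraction: float, region_weight_g: float | None) -> float:
    """mass_mg = relative_fraction × regional pancreas weight (g) × 1000.

    Missing weight yields NaN (a missing-data sentinel, never zero).
    """
    if not 0.0 <= relative_fraction <= 1.0:
        raise ValueError("relative_fraction must lie in [0, 1]")
    if region_weight_g is None or np.isnan(region_weight_g):
        return MASS_MISSING
    if region_weight_g < 0:
        raise ValueError("region weight must be non-negative")
    return relative_fraction * region_weight_g * 1000.0


def _exp_model(x, a, b):
    return a * np.exp(b * x)


def size_binned_profile(
    islets: pd.DataFrame,
    properties: list[str],
    n_bins: int = DEFAULT_N_BINS,
) -> dict:
    """Bin islets into equal-width log2(area) bins and fit y = a·exp(b·x)
    to the per-bin property means (x = log2 area in µm²).

    Returns bin edges/centres, per-bin counts and means, and per-property
    fit results; the fit is skipped (with a warning) when fewer than two
    bins are occupied.
    """
    log2a = np.log2(islets["area_um2"].to_numpy(float))
    lo, hi = log2a.min(), log2a.max()
    if hi <= lo:
        hi = lo + 1e-9
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(log2a, edges) - 1, 0, n_bins - 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.bincount(idx, minlength=n_bins)
    result: dict = {
        "bin_edges_log2": edges.tolist(),
        "bin_centers_log2": centers.tolist(),
        "bin_counts": counts.tolist(),
        "bin_area_um2": [
            float(islets["area_um2"].to_numpy(float)[idx == b].sum())
            for b in range(n_bins)
        ],
        "properties": {},
    }
    occupied = counts > 0
    for prop in properties:
        vals = islets[prop].to_numpy(float)
        means = np.full(n_bins, np.nan)
        for b in np.nonzero(occupied)[0]:
            means[b] = vals[idx == b].mean()
        entry: dict = {"bin_means": means.tolist()}
        x = centers[occupied]
        y = means[occupied]
        if occupied.sum() < 2:
            warnings.warn(
                f"fewer than 2 occupied bins for {prop!r}; exponential fit skipped"
            )
            entry["fit"] = None
        else:
            try:
                # log-linear seed when all means are positive
                if np.all(y > 0):
                    b1, b0 = np.polyfit(x, np.log(y), 1)
                    p0 = (float(np.exp(b0)), float(b1))
                else:
                    p0 = (float(y.mean()), 0.0)
                popt, _ = optimize.curve_fit(_exp_model, x, y, p0=p0, maxfev=20000)
                pred = _exp_model(x, *popt)
                ss_res = float(((y - pred) ** 2).sum())
                ss_tot = float(((y - y.mean()) ** 2).sum())
                r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
                entry["fit"] = {"a": float(popt[0]), "b": float(popt[1]), "r2": r2}
            except RuntimeError:
                warnings.warn(f"exponential fit did not converge for {prop!r}")
                entry["fit"] = None
        result["properties"][prop] = entry
    return result
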