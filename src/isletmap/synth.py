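"""Synthetic cohort generator.

Produces tissue polygons, islet tables with ground-truth composition and
cluster labels, rendered stain masks, and cell point sets whose
statistics follow per-stage templates (right-skewed islet sizes,
stage-dependent insulin-deficient fractions, GCG-deficient small islets,
PPY-dominant islets in the pancreatic head, overdispersed islet-associated
CD45 counts with rare insulitic islets, and stage-dependent spatial
thinning), so every downstream stage is testable without any download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
import shapely
import shapely.affinity
from scipy import stats
from shapely.geometry import Polygon, box

from .core import (
    CHANNELS_9,
    HORMONES_8,
    MAJOR_CLUSTERS,
    MIN_ISLET_AREA_UM2,
    REGIONS,
    STAGES,
    StainMask,
    TissueSection,
)
from .hormones import SUBSET_THRESHOLD

__all__ = [
    "CD45Model",
    "StageTemplate",
    "PlacementError",
    "generate_tissue",
    "generate_islets",
    "render_stain_masks",
    "generate_cells",
    "load_template",
    "builtin_template_names",
]


class PlacementError(RuntimeError):
    """Non-overlapping islet placement failed after bounded retries."""


@dataclass
class CD45Model:
    """Islet-associated CD45 count model.

    ``p_any_cd45`` is the overall fraction of islets with >= 1 associated
    CD45+ cell; counts among positive, non-insulitic islets follow a
    negative binomial (overdispersed) clipped below the insulitis
    threshold; insulitic islets (overall fraction ``p_insulitic``) draw
    15 plus a negative-binomial excess.
    """

    p_any_cd45: float = 0.25
    nb_mean: float = 2.0
    nb_dispersion: float = 1.0  # NB size parameter r; smaller = heavier tail
    p_insulitic: float = 0.0

    def validate(self) -> None:
        for name in ("p_any_cd45", "p_insulitic"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("negative-binomial parameters must be positive")


#: Per-cluster mean staining-area fractions (the 9 channels).  Values are
#: transcribed qualitatively from the study's cluster property summaries;
#: channels whose mean falls below the 1% threshold are drawn strictly
#: sub-threshold so subset rules recover cluster identity exactly.
DEFAULT_HORMONE_RULES: dict[str, dict[str, float]] = {
    "I": {"CHGA": 0.85, "ProINS_total": 0.55, "ProINS_hi": 0.20, "INS": 0.35,
          "IAPP": 0.30, "ProGCG": 0.28, "GCG": 0.15, "SST": 0.08, "PPY": 0.004},
    "II": {"CHGA": 0.85, "ProINS_total": 0.45, "ProINS_hi": 0.15, "INS": 0.30,
           "IAPP": 0.25, "ProGCG": 0.30, "GCG": 0.16, "SST": 0.08, "PPY": 0.004},
    "III": {"CHGA": 0.60, "ProINS_total": 0.45, "ProINS_hi": 0.15, "INS": 0.30,
            "IAPP": 0.25, "ProGCG": 0.004, "GCG": 0.004, "SST": 0.08, "PPY": 0.35},
    "IV": {"CHGA": 0.30, "ProINS_total": 0.004, "ProINS_hi": 0.002, "INS": 0.004,
           "IAPP": 0.004, "ProGCG": 0.004, "GCG": 0.004, "SST": 0.06, "PPY": 0.85},
    "V-A": {"CHGA": 0.80, "ProINS_total": 0.004, "ProINS_hi": 0.002, "INS": 0.004,
            "IAPP": 0.004, "ProGCG": 0.55, "GCG": 0.28, "SST": 0.12, "PPY": 0.004},
    "V-BC": {"CHGA": 0.80, "ProINS_total": 0.004, "ProINS_hi": 0.002, "INS": 0.004,
             "IAPP": 0.004, "ProGCG": 0.50, "GCG": 0.25, "SST": 0.14, "PPY": 0.004},
}

#: Clusters that are insulin-deficient / constitutively GCG-deficient.
IDI_CLUSTERS = ("IV", "V-A", "V-BC")
GCG_NEG_CLUSTERS = ("III", "IV")


@dataclass
class StageTemplate:
    """Generative parameters for one donor-group/region combination.

    Size distribution is log-normal on ln(µm²), truncated at the
    pipeline's 1,000 µm² minimum islet area.  ``donor_jitter`` scales
    donor-level variability (the study prints group summaries only, so
    the default is a declared guess).
    """

    stage_label: str = "Ctrl"
    region: str = "PT"
    islet_density_per_mm2: float = 2.0
    size_log_mu: float = float(np.log(3200.0))
    size_log_sigma: float = 0.85
    frac_IDI: float = 0.03
    frac_GCG_deficient: float = 0.34
    frac_PPY_dominant: float = 0.01
    cd45_model: CD45Model = field(default_factory=CD45Model)
    spatial_mode: str = "uniform"
    cluster_weights: dict[str, float] = field(
        default_factory=lambda: {
            "I": 0.70, "II": 0.26, "III": 0.005, "IV": 0.01,
            "V-A": 0.015, "V-BC": 0.01,
        }
    )
    hormone_rules: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: dict(v) for c, v in DEFAULT_HORMONE_RULES.items()}
    )
    cell_density_per_mm2: float = 9000.0
    donor_jitter: float = 0.1
    pancreas_region_weight_g: float = 30.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.stage_label not in STAGES:
            raise ValueError(f"unknown stage {self.stage_label!r}")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.islet_density_per_mm2 < 0:
            raise ValueError("islet density must be non-negative")
        if self.spatial_mode not in ("uniform", "thinned_patches"):
            raise ValueError(f"unknown spatial_mode {self.spatial_mode!r}")
        for name in ("frac_IDI", "frac_GCG_deficient", "frac_PPY_dominant"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        self.cd45_model.validate()
        w = self.cluster_weights
        missing = set(MAJOR_CLUSTERS) - set(w)
        if missing:
            raise ValueError(f"cluster_weights missing {sorted(missing)}")
        total = sum(w.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"cluster weights sum to {total}, expected 1")
        idi = sum(w[c] for c in IDI_CLUSTERS)
        if not np.isclose(idi, self.frac_IDI, atol=1e-6):
            raise ValueError(
                f"frac_IDI={self.frac_IDI} inconsistent with IDI cluster "
                f"weights summing to {idi}"
            )
        if not np.isclose(w["IV"], self.frac_PPY_dominant, atol=1e-6):
            raise ValueError(
                "frac_PPY_dominant must equal the cluster IV weight"
            )
        gcg_neg = sum(w[c] for c in GCG_NEG_CLUSTERS)
        if self.frac_GCG_deficient < gcg_neg - 1e-9:
            raise ValueError(
                "frac_GCG_deficient below the constitutively GCG-negative "
                f"cluster mass {gcg_neg}"
            )

    # -- derived sampling probabilities ------------------------------------
    @property
    def p_gcg_deficient_beta(self) -> float:
        """P(GCG-deficient) among beta-positive (I/II) islets."""
        w = self.cluster_weights
        gcg_neg = sum(w[c] for c in GCG_NEG_CLUSTERS)
        beta = w["I"] + w["II"]
        if beta <= 0:
            return 0.0
        return float(np.clip((self.frac_GCG_deficient - gcg_neg) / beta, 0.0, 1.0))

    def cd45_positive_prob(self, cluster: str) -> float:
        """P(>=1 CD45) by cluster, chosen so the pooled prevalence equals
        ``p_any_cd45``: clusters II/V-A carry CD45 preferentially, then
        III/IV, then I/V-BC."""
        w = self.cluster_weights
        p_any = self.cd45_model.p_any_cd45
        tiers = [("II", "V-A"), ("III", "IV"), ("I", "V-BC")]
        remaining = p_any
        for tier in tiers:
            mass = sum(w[c] for c in tier)
            q = min(1.0, remaining / mass) if mass > 0 else 0.0
            if cluster in tier:
                return q
            remaining -= q * mass
        raise ValueError(f"unknown cluster {cluster!r}")

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "cd45_model"}
        d["cd45_model"] = dict(self.cd45_model.__dict__)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StageTemplate":
        d = dict(d)
        d["cd45_model"] = CD45Model(**d.get("cd45_model", {}))
        return cls(**d)

    def with_donor_jitter(self, rng: np.random.Generator) -> "StageTemplate":
        """A donor-level perturbation of the group template (log-normal on
        density and size, logit-ish on fractions)."""
        j = self.donor_jitter
        if j <= 0:
            return replace(self)
        density = self.islet_density_per_mm2 * float(rng.lognormal(0.0, j))
        mu = self.size_log_mu + float(rng.normal(0.0, j * 0.2))
        return replace(self, islet_density_per_mm2=density, size_log_mu=mu)


def builtin_template_names() -> list[str]:
    root = resources.files("isletmap") / "templates"
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".json"))


def load_template(name_or_path: str) -> StageTemplate:
    """Load a stage template: a built-in preset name (e.g. ``Ctrl_PT``)
    or a path to a JSON file."""
    root = resources.files("isletmap") / "templates"
    candidate = root / f"{name_or_path}.json"
    try:
        text = candidate.read_text()
    except (FileNotFoundError, OSError):
        with open(name_or_path) as fh:
            text = fh.read()
    return StageTemplate.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# tissue generation
# ---------------------------------------------------------------------------

def generate_tissue(
    seed: int,
    width_mm: float,
    height_mm: float,
    irregularity: float = 0.3,
    region: str = "PT",
    donor_id: str = "",
    stage: str = "Ctrl",
    pancreas_region_weight_g: float | None = None,
) -> TissueSection:
    """Random simple tissue polygon inside a width×height bounding box.

    ``irregularity`` = 0 yields the exact rectangle; larger values pull
    the outline inward with smooth periodic noise (area stays within
    [1 - irregularity, 1] of the box).  Deterministic for a fixed seed.
    """
    if width_mm <= 0 or height_mm <= 0:
        raise ValueError("tissue dimensions must be positive")
    if not 0.0 <= irregularity <= 1.0:
        raise ValueError("irregularity must lie in [0, 1]")
    w, h = width_mm * 1000.0, height_mm * 1000.0
    if irregularity == 0.0:
        poly = box(0.0, 0.0, w, h)
    else:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7919]))
        n = 96
        theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        # smooth periodic noise in [0, 1] from a few Fourier harmonics
        noise = np.zeros(n)
        for m in range(1, 6):
            noise += rng.uniform(0, 1.0 / m) * np.cos(m * theta + rng.uniform(0, 2 * np.pi))
        lo, hi = noise.min(), noise.max()
        noise = (noise - lo) / (hi - lo) if hi > lo else np.zeros(n)
        shrink = 1.0 - irregularity * noise
        cx, cy = w / 2.0, h / 2.0
        # distance from centre to the rectangle edge along each direction
        with np.errstate(divide="ignore"):
            tx = np.where(np.cos(theta) != 0, (w / 2.0) / np.abs(np.cos(theta)), np.inf)
            ty = np.where(np.sin(theta) != 0, (h / 2.0) / np.abs(np.sin(theta)), np.inf)
        r_edge = np.minimum(tx, ty)
        r = r_edge * shrink
        poly = Polygon(np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)]))
        if not poly.is_valid:
            poly = poly.buffer(0)
    return TissueSection(
        boundary=poly,
        region=region,
        donor_id=donor_id,
        stage=stage,
        pancreas_region_weight_g=pancreas_region_weight_g,
    )


# ---------------------------------------------------------------------------
# interval-set layout of channels within one islet
# ---------------------------------------------------------------------------

def _merge(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    out: list[tuple[float, float]] = []
    for s, e in sorted(i for i in intervals if i[1] > i[0]):
        if out and s <= out[-1][1] + 1e-12:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _measure(intervals: list[tuple[float, float]]) -> float:
    return sum(e - s for s, e in intervals)


def _complement(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    out, pos = [], 0.0
    for s, e in _merge(intervals):
        if s > pos:
            out.append((pos, s))
        pos = max(pos, e)
    if pos < 1.0:
        out.append((pos, 1.0))
    return out


def _take(intervals: list[tuple[float, float]], amount: float):
    """First ``amount`` of measure from an interval list (in order)."""
    taken = []
    for s, e in intervals:
        if amount <= 1e-15:
            break
        span = min(e - s, amount)
        taken.append((s, s + span))
        amount -= span
    return taken, amount


def channel_layout(fractions: dict[str, float]) -> dict[str, list[tuple[float, float]]]:
    """Deterministic arc layout of the nine channels on the unit interval.

    The islet's area is identified with [0, 1); beta-cell channels share
    a leading arc (nested: INS/IAPP/ProINS_hi inside ProINS_total), then
    alpha (GCG inside ProGCG), delta (SST), gamma (PPY) arcs.  CHGA
    covers everything except a hole carved preferentially from regions
    already covered by another islet-defining stain so that the
    six-stain union tiles (nearly) the whole islet.
    """
    f = fractions
    beta = max(f["ProINS_total"], f["ProINS_hi"], f["INS"], f["IAPP"])
    alpha = max(f["ProGCG"], f["GCG"])
    a0, a1 = beta, beta + alpha
    d0, d1 = a1, a1 + f["SST"]
    g0, g1 = d1, d1 + f["PPY"]
    layout: dict[str, list[tuple[float, float]]] = {
        "ProINS_total": [(0.0, f["ProINS_total"])],
        "ProINS_hi": [(0.0, f["ProINS_hi"])],
        "INS": [(0.0, f["INS"])],
        "IAPP": [(0.0, f["IAPP"])],
        "ProGCG": [(a0, a0 + f["ProGCG"])],
        "GCG": [(a0, a0 + f["GCG"])],
        "SST": [(d0, d1)],
        "PPY": [(g0, g1)],
    }
    covered_by_defining = _merge(
        layout["ProINS_total"] + layout["INS"] + layout["GCG"]
        + layout["SST"] + layout["PPY"]
    )
    hole = 1.0 - f["CHGA"]
    taken, leftover = _take(covered_by_defining, hole)
    if leftover > 1e-12:
        extra, _ = _take(_complement(covered_by_defining), leftover)
        taken = _merge(taken + extra)
    layout["CHGA"] = _complement(taken)
    return layout


def union_fractions(layout: dict[str, list[tuple[float, float]]]) -> tuple[float, float]:
    """(six-stain defining union, eight-hormone endocrine union) measures."""
    defining = _merge(
        sum((layout[c] for c in ("CHGA", "ProINS_total", "INS", "GCG", "SST", "PPY")), [])
    )
    endocrine = _merge(sum((layout[c] for c in HORMONES_8), []))
    return _measure(defining), _measure(endocrine)


# ---------------------------------------------------------------------------
# islet generation
# ---------------------------------------------------------------------------

def _sample_truncated_lognormal(rng, mu, sigma, n, floor=MIN_ISLET_AREA_UM2):
    """Areas ~ LogNormal(mu, sigma) conditioned on area >= floor (inverse CDF)."""
    z_floor = (np.log(floor) - mu) / sigma
    p_floor = stats.norm.cdf(z_floor)
    u = rng.uniform(p_floor, 1.0, size=n)
    return np.exp(mu + sigma * stats.norm.ppf(u))


def _star_polygon(rng, area_um2, n_vertices=24, roughness=0.18, max_elong=1.35):
    """Noisy star-convex polygon with controllable elongation, scaled to
    the requested area and centred at the origin."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    radii = np.ones(n_vertices)
    for m in range(2, 6):
        radii += rng.uniform(0.0, roughness / (m - 1)) * np.cos(
            m * theta + rng.uniform(0.0, 2.0 * np.pi)
        )
    radii = np.clip(radii, 0.3, None)
    x = radii * np.cos(theta)
    y = radii * np.sin(theta)
    e = rng.uniform(1.0, max_elong)
    phi = rng.uniform(0.0, np.pi)
    xr = (x * np.cos(phi) - y * np.sin(phi)) * e
    yr = (x * np.sin(phi) + y * np.cos(phi)) / e
    poly = Polygon(np.column_stack([xr, yr]))
    if not poly.is_valid:
        poly = poly.convex_hull
    scale = np.sqrt(area_um2 / poly.area)
    return shapely.affinity.scale(poly, xfact=scale, yfact=scale, origin=(0, 0))


def _thinning_field(rng, bounds, n_patches=5):
    """Random depletion patches: returns (centers, radii, keep_prob)."""
    x0, y0, x1, y1 = bounds
    extent = min(x1 - x0, y1 - y0)
    centers = np.column_stack(
        [rng.uniform(x0, x1, n_patches), rng.uniform(y0, y1, n_patches)]
    )
    radii = rng.uniform(0.12, 0.30, n_patches) * extent
    return centers, radii, 0.2


def generate_islets(
    template: StageTemplate,
    tissue: TissueSection,
    seed: int,
    max_attempts_per_islet: int = 200,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the islet table and its ground truth for one section.

    Realized islet count is Poisson(density × parenchymal area); islets
    are placed without overlap (>= 10 µm gaps) strictly inside the
    tissue.  Returns ``(islets, truth)`` where ``truth`` carries the true
    cluster/subset labels and CD45 counts per islet.
    """
    template.validate()
    if tissue.parenchymal_area_mm2 < 1.0:
        raise ValueError("tissue area must be at least 1 mm²")
    ss = np.random.SeedSequence([int(seed), 104729])
    r_count, r_size, r_place, r_shape, r_comp, r_cd45 = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    n = int(r_count.poisson(template.islet_density_per_mm2 * tissue.parenchymal_area_mm2))
    cols_truth = ["islet_id", "cluster", "is_IDI", "is_GCG_deficient",
                  "is_PPY_dominant", "cd45_total", "insulitic"]
    if n == 0:
        return (
            pd.DataFrame(columns=_islet_table_columns()),
            pd.DataFrame(columns=cols_truth),
        )

    areas = _sample_truncated_lognormal(
        r_size, template.size_log_mu, template.size_log_sigma, n
    )
    order = np.argsort(-areas)  # place large islets first
    areas = areas[order]

    # placement ------------------------------------------------------------
    boundary = tissue.boundary.exterior
    x0, y0, x1, y1 = tissue.boundary.bounds
    thin_centers = thin_radii = None
    keep_prob = 1.0
    if template.spatial_mode == "thinned_patches":
        thin_centers, thin_radii, keep_prob = _thinning_field(
            r_place, tissue.boundary.bounds
        )
    placed_xy: list[np.ndarray] = []
    placed_r: list[float] = []
    polys: list[Polygon] = []
    for i in range(n):
        r_eff = np.sqrt(areas[i] / np.pi) * 1.6  # bounding-radius guess
        shape0 = _star_polygon(r_shape, areas[i])
        verts = np.asarray(shape0.exterior.coords)
        r_eff = float(np.hypot(verts[:, 0], verts[:, 1]).max())
        ok = False
        for _ in range(max_attempts_per_islet):
            cx = r_place.uniform(x0, x1)
            cy = r_place.uniform(y0, y1)
            if thin_centers is not None:
                d = np.hypot(thin_centers[:, 0] - cx, thin_centers[:, 1] - cy)
                if np.any(d < thin_radii) and r_place.uniform() > keep_prob:
                    continue
            p = shapely.Point(cx, cy)
            if not tissue.boundary.covers(p):
                continue
            if boundary.distance(p) < r_eff + 15.0:
                continue
            if placed_xy:
                arr = np.asarray(placed_xy)
                rad = np.asarray(placed_r)
                good = bool(
                    np.all(
                        np.hypot(arr[:, 0] - cx, arr[:, 1] - cy)
                        >= rad + r_eff + 10.0
                    )
                )
            else:
                good = True
            if good:
                placed_xy.append(np.array([cx, cy]))
                placed_r.append(r_eff)
                polys.append(
                    Polygon(np.asarray(shape0.exterior.coords) + [cx, cy])
                )
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place islet {i} of {n} after "
                f"{max_attempts_per_islet} attempts (density too high?)"
            )

    # composition ----------------------------------------------------------
    weights = np.array([template.cluster_weights[c] for c in MAJOR_CLUSTERS])
    clusters = r_comp.choice(len(MAJOR_CLUSTERS), size=n, p=weights / weights.sum())
    cluster_names = np.array(MAJOR_CLUSTERS)[clusters]
    p_gd = template.p_gcg_deficient_beta
    rows = []
    truth_rows = []
    m = template.cd45_model
    for i in range(n):
        cname = str(cluster_names[i])
        rules = template.hormone_rules[cname]
        is_idi = cname in IDI_CLUSTERS
        gcg_def = cname in GCG_NEG_CLUSTERS or (
            cname in ("I", "II") and r_comp.uniform() < p_gd
        )
        fr: dict[str, float] = {}
        for ch in CHANNELS_9:
            mean = rules[ch]
            if mean < SUBSET_THRESHOLD:
                fr[ch] = float(r_comp.uniform(0.0, 0.8 * SUBSET_THRESHOLD))
            else:
                kappa = 60.0
                fr[ch] = float(r_comp.beta(mean * kappa, (1.0 - mean) * kappa))
        if gcg_def:
            fr["GCG"] = float(r_comp.uniform(0.0, 0.8 * SUBSET_THRESHOLD))
            if cname in ("I", "II"):
                fr["ProGCG"] = min(fr["ProGCG"], 0.05)
        # nesting and coverage constraints
        fr["INS"] = min(fr["INS"], fr["ProINS_total"])
        fr["IAPP"] = min(fr["IAPP"], fr["ProINS_total"])
        fr["ProINS_hi"] = min(fr["ProINS_hi"], fr["ProINS_total"])
        fr["GCG"] = min(fr["GCG"], fr["ProGCG"])
        arcs = fr["ProINS_total"] + fr["ProGCG"] + fr["SST"] + fr["PPY"]
        if arcs > 0.98:
            scale = 0.98 / arcs
            for ch in ("ProINS_total", "ProINS_hi", "INS", "IAPP",
                       "ProGCG", "GCG", "SST", "PPY"):
                fr[ch] *= scale
        layout = channel_layout(fr)
        _, endocrine = union_fractions(layout)

        # CD45 counts
        q = template.cd45_positive_prob(cname)
        insulitic = False
        cd45 = 0
        if cname == "II" and template.cluster_weights["II"] > 0:
            p_ins = min(1.0, m.p_insulitic / template.cluster_weights["II"])
            insulitic = bool(r_cd45.uniform() < p_ins)
        if insulitic:
            cd45 = 15 + int(r_cd45.negative_binomial(
                m.nb_dispersion, m.nb_dispersion / (m.nb_dispersion + 5.0)
            ))
        elif r_cd45.uniform() < q:
            p_nb = m.nb_dispersion / (m.nb_dispersion + max(m.nb_mean - 1.0, 1e-9))
            cd45 = min(14, 1 + int(r_cd45.negative_binomial(m.nb_dispersion, p_nb)))

        poly = polys[i]
        area = float(poly.area)
        from .segmentation import shape_descriptors

        _, perim, circ, sol, ar = shape_descriptors(poly)
        density = template.cell_density_per_mm2 * (area / 3000.0) ** -0.1
        if is_idi:
            density *= 1.35
        density *= float(r_comp.lognormal(0.0, 0.08))
        nuclei = max(1, int(round(density * area / 1e6)))
        c = poly.centroid
        row = {
            "islet_id": i,
            "donor_id": tissue.donor_id,
            "region": tissue.region,
            "stage": tissue.stage,
            "centroid_x_um": float(c.x),
            "centroid_y_um": float(c.y),
            "area_um2": area,
            "perimeter_um": perim,
            "circularity": circ,
            "solidity": sol,
            "aspect_ratio": ar,
            "equivalent_diameter_um": 2.0 * float(np.sqrt(area / np.pi)),
            "nuclei_count": nuclei,
            "cell_density_per_mm2": nuclei / (area / 1e6),
            "frac_endocrine": endocrine,
            "polygon_wkt": poly.wkt,
        }
        for ch in CHANNELS_9:
            row[f"frac_{ch}"] = fr[ch]
        rows.append(row)
        truth_rows.append(
            {
                "islet_id": i,
                "cluster": cname,
                "is_IDI": is_idi,
                "is_GCG_deficient": bool(gcg_def),
                "is_PPY_dominant": cname == "IV",
                "cd45_total": cd45,
                "insulitic": insulitic,
            }
        )
    islets = pd.DataFrame(rows, columns=_islet_table_columns())
    truth = pd.DataFrame(truth_rows, columns=cols_truth)
    return islets, truth


def _islet_table_columns() -> list[str]:
    return (
        [
            "islet_id", "donor_id", "region", "stage",
            "centroid_x_um", "centroid_y_um", "area_um2", "perimeter_um",
            "circularity", "solidity", "aspect_ratio",
            "equivalent_diameter_um", "nuclei_count", "cell_density_per_mm2",
        ]
        + [f"frac_{ch}" for ch in CHANNELS_9]
        + ["frac_endocrine", "polygon_wkt"]
    )


# ---------------------------------------------------------------------------
# raster rendering
# ---------------------------------------------------------------------------

def render_stain_masks(
    islets: pd.DataFrame,
    pixel_size_um: float,
    channels: tuple[str, ...] = CHANNELS_9,
    shape: tuple[int, int] | None = None,
) -> dict[str, StainMask]:
    """Rasterize per-channel binary stain masks from the islet table.

    Each islet's pixels are ranked by angle around its centroid (with a
    deterministic per-islet offset) and assigned to channels through the
    same arc layout that produced the table fractions, so mask area
    fractions agree with the recorded ground truth to within raster
    resolution.
    """
    if not 0 < pixel_size_um <= 5.0:
        raise ValueError(
            "pixel_size_um must be in (0, 5] so the smallest islet spans >= 2 px"
        )
    from .hormones import rasterize_polygon

    if shape is None:
        pad = 20.0
        if len(islets):
            max_x = max(
                shapely.from_wkt(w).bounds[2] for w in islets["polygon_wkt"]
            )
            max_y = max(
                shapely.from_wkt(w).bounds[3] for w in islets["polygon_wkt"]
            )
        else:
            max_x = max_y = 100.0
        shape = (
            int(np.ceil((max_y + pad) / pixel_size_um)),
            int(np.ceil((max_x + pad) / pixel_size_um)),
        )
    masks = {ch: np.zeros(shape, dtype=bool) for ch in channels}
    for _, row in islets.iterrows():
        poly = shapely.from_wkt(row["polygon_wkt"])
        footprint = rasterize_polygon(poly, shape, pixel_size_um)
        rr, cc = np.nonzero(footprint)
        if len(rr) == 0:
            continue
        cx = row["centroid_x_um"] / pixel_size_um - 0.5
        cy = row["centroid_y_um"] / pixel_size_um - 0.5
        offset = (int(row["islet_id"]) * 2654435761 % 360) * np.pi / 180.0
        ang = np.mod(np.arctan2(rr - cy, cc - cx) + offset, 2.0 * np.pi)
        rank = np.argsort(ang, kind="stable")
        npix = len(rr)
        pos = (np.arange(npix) + 0.5) / npix  # arc position of each rank
        fr = {ch: float(row[f"frac_{ch}"]) for ch in CHANNELS_9}
        layout = channel_layout(fr)
        for ch in channels:
            sel = np.zeros(npix, dtype=bool)
            for s, e in layout[ch]:
                sel |= (pos >= s) & (pos < e)
            idx = rank[sel]
            masks[ch][rr[idx], cc[idx]] = True
    return {
        ch: StainMask(data=m, pixel_size_um=pixel_size_um, channel=ch)
        for ch, m in masks.items()
    }


# ---------------------------------------------------------------------------
# cell point sets
# ---------------------------------------------------------------------------

def _sample_in_polygon(rng, poly, n, max_iter=1000):
    """Uniform points inside a polygon by bounding-box rejection."""
    if n <= 0:
        return np.empty((0, 2))
    x0, y0, x1, y1 = poly.bounds
    out = []
    remaining = n
    for _ in range(max_iter):
        m = max(remaining * 3, 16)
        cand = np.column_stack(
            [rng.uniform(x0, x1, m), rng.uniform(y0, y1, m)]
        )
        keep = shapely.covers(poly, shapely.points(cand))
        got = cand[keep][:remaining]
        if len(got):
            out.append(got)
            remaining -= len(got)
        if remaining == 0:
            break
    if remaining:
        raise RuntimeError("rejection sampling failed to fill the polygon")
    return np.concatenate(out)


def generate_cells(
    islets: pd.DataFrame,
    truth: pd.DataFrame,
    template: StageTemplate,
    seed: int,
    peri_margin_um: float = 20.0,
    intra_fraction: float = 0.4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place nuclei and CD45+ points for each islet.

    Nuclei are uniform within the islet polygon at the islet's recorded
    cell density; the ground-truth CD45 count is split binomially into
    intra-islet points and points in the 20 µm peri-islet annulus.
    Returns ``(cells, cell_truth)`` with per-islet true intra/peri counts.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 15485863]))
    xs, ys, classes, owners = [], [], [], []
    truth_rows = []
    cd45_by_id = dict(zip(truth["islet_id"], truth["cd45_total"])) if len(truth) else {}
    for _, row in islets.iterrows():
        poly = shapely.from_wkt(row["polygon_wkt"])
        iid = int(row["islet_id"])
        n_nuc = int(row["nuclei_count"])
        pts = _sample_in_polygon(rng, poly, n_nuc)
        cd45_total = int(cd45_by_id.get(iid, 0))
        n_intra = int(rng.binomial(cd45_total, intra_fraction)) if cd45_total else 0
        n_peri = cd45_total - n_intra
        intra_pts = _sample_in_polygon(rng, poly, n_intra)
        annulus = poly.buffer(peri_margin_um).difference(poly)
        peri_pts = _sample_in_polygon(rng, annulus, n_peri)
        # peri region also holds ordinary (exocrine) nuclei
        n_peri_nuc = max(
            n_peri, int(round(template.cell_density_per_mm2 * annulus.area / 1e6 * 0.5))
        )
        peri_nuc = _sample_in_polygon(rng, annulus, n_peri_nuc)
        for arr, cls in (
            (pts, "nucleus"),
            (peri_nuc, "nucleus"),
            (intra_pts, "CD45"),
            (peri_pts, "CD45"),
        ):
            xs.append(arr[:, 0])
            ys.append(arr[:, 1])
            classes.extend([cls] * len(arr))
            owners.extend([iid] * len(arr))
        truth_rows.append(
            {
                "islet_id": iid,
                "cd45_intra_true": n_intra,
                "cd45_peri_true": n_peri,
                "nuclei_intra_true": n_nuc + n_intra,
                "nuclei_peri_true": n_peri_nuc + n_peri,
            }
        )
    cells = pd.DataFrame(
        {
            "x_um": np.concatenate(xs) if xs else np.empty(0),
            "y_um": np.concatenate(ys) if ys else np.empty(0),
            "class": classes,
            "islet_id_true": owners,
        }
    )
    return cells, pd.DataFrame(
        truth_rows,
        columns=["islet_id", "cd45_intra_true", "cd45_peri_true",
                 "nuclei_intra_true", "nuclei_peri_true"],
    )
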