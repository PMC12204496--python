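import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from isletmap.spatial import (
    DELAUNAY_FALLBACK_AREA_UM2,
    DELAUNAY_FALLBACK_DISTANCE_UM,
    back_project,
    cd45_bin_label,
    circle_tissue_weight,
    cluster_delaunay,
    delaunay_metrics,
    fractal_dimension,
    ripley_modified,
)


def mc_circle_weight(center, radius, tissue, n=100_000, seed=0):
    """Monte-Carlo oracle for the circle∩tissue area fraction."""
    import shapely

    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, 2 * np.pi, n)
    r = radius * np.sqrt(rng.uniform(0, 1, n))
    pts = np.column_stack(
        [center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)]
    )
    return shapely.contains(tissue, shapely.points(pts)).mean()


class TestBoundaryWeight:
    def test_interior_circle_weight_one(self):
        tissue = box(0, 0, 10_000, 10_000)
        assert circle_tissue_weight(np.array([5000.0, 5000.0]), 1000, tissue) == 1.0

    @pytest.mark.parametrize("center", [(100, 200), (500, 500), (50, 9950)])
    def test_against_monte_carlo_oracle(self, center):
        tissue = box(0, 0, 10_000, 10_000)
        w = circle_tissue_weight(np.array(center, float), 800, tissue)
        mc = mc_circle_weight(center, 800, tissue)
        assert w == pytest.approx(mc, rel=0.01)

    def test_monotone_nonincreasing_toward_boundary(self):
        tissue = box(0, 0, 10_000, 10_000)
        r = 1000.0
        ws = [
            circle_tissue_weight(np.array([x, 5000.0]), r, tissue)
            for x in (5000, 2000, 1200, 800, 400, 100)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(ws, ws[1:]))


class TestRipley:
    def test_single_pair_below_distance_k_zero(self):
        tissue = box(0, 0, 10_000, 10_000)
        pts = np.array([[3000.0, 5000.0], [7000.0, 5000.0]])
        curve = ripley_modified(pts, tissue, np.array([500.0, 1000.0]))
        assert np.all(curve.k_values == 0.0)

    def test_csr_k_near_one_single_seed(self):
        tissue = box(0, 0, 20_000, 20_000)
        rng = np.random.default_rng(123)
        pts = rng.uniform(0, 20_000, (2000, 2))
        curve = ripley_modified(pts, tissue, np.linspace(400, 2000, 9))
        assert curve.k_values.mean() == pytest.approx(1.0, abs=0.1)

    def test_outside_centroid_rejected_with_warning(self):
        tissue = box(0, 0, 1000, 1000)
        pts = np.array([[500.0, 500.0], [600.0, 500.0], [5000.0, 5000.0]])
        with pytest.warns(UserWarning, match="outside"):
            curve = ripley_modified(pts, tissue, np.array([200.0]))
        assert curve.slide_density_per_um2 == pytest.approx(2 / 1e6)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 5000, (300, 2))
        tissue = box(0, 0, 5000, 5000)
        radii = np.linspace(400, 1500, 5)
        k1 = ripley_modified(pts, tissue, radii).k_values
        shifted = pts + [10_000, 3000]
        tissue2 = box(10_000, 3000, 15_000, 8000)
        k2 = ripley_modified(shifted, tissue2, radii).k_values
        assert np.allclose(k1, k2, rtol=1e-9)

    def test_auc_trapezoid(self):
        tissue = box(0, 0, 20_000, 20_000)
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 20_000, (500, 2))
        curve = ripley_modified(pts, tissue, np.linspace(400, 2000, 5))
        assert curve.auc == pytest.approx(
            np.trapezoid(curve.k_values, curve.radii_um)
        )

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ripley_modified(np.array([[1.0, 1.0]]), box(0, 0, 10, 10), np.array([1.0]))


class TestFractalDimension:
    def test_exact_quadratic_counts(self):
        radii = np.geomspace(400, 10_000, 20)
        counts = 3.2e-5 * radii**2
        assert fractal_dimension(radii, counts) == pytest.approx(2.0, abs=1e-9)

    def test_linear_pattern_slope_one(self):
        # points on a line: counts grow linearly with radius
        pts = np.column_stack([np.linspace(100, 19_900, 2000), np.full(2000, 5000.0)])
        tissue = box(0, 0, 20_000, 10_000)
        curve = ripley_modified(pts, tissue, np.geomspace(400, 3000, 12))
        slope = fractal_dimension(curve.radii_um, curve.mean_adjusted_counts)
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_small_radii_excluded(self):
        radii = np.array([400.0, 500.0, 600.0, 1000.0, 2000.0, 4000.0])
        counts = np.array([99.0, 99.0, 99.0, 1.0, 4.0, 16.0])  # junk below 600
        assert fractal_dimension(radii, counts) == pytest.approx(2.0, abs=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fractal_dimension(np.array([700.0, 800.0]), np.array([1.0, 2.0]))


class TestDelaunayMetrics:
    def test_fallback_assignment(self):
        pts = np.array([[0.0, 0.0], [500.0, 0.0], [6000.0, 3000.0]])
        df = delaunay_metrics(pts)
        rec = df.iloc[2]
        assert bool(rec["is_fallback"])
        assert rec["delaunay_mean_dist_um"] == DELAUNAY_FALLBACK_DISTANCE_UM
        assert rec["delaunay_mean_area_um2"] == pytest.approx(np.pi * 16e6)

    def test_hexagonal_lattice_mean_distance(self):
        a = 500.0
        pts = np.array(
            [
                [i * a + (j % 2) * a / 2, j * a * np.sqrt(3) / 2]
                for i in range(12)
                for j in range(12)
            ]
        )
        df = delaunay_metrics(pts)
        interior = (
            (pts[:, 0] > 1200) & (pts[:, 0] < 4200)
            & (pts[:, 1] > 1200) & (pts[:, 1] < 3800)
        )
        assert interior.sum() > 10
        assert np.allclose(df["delaunay_mean_dist_um"][interior], a)

    def test_equilateral_triangle_area(self):
        s = 1000.0
        pts = np.array([[0.0, 0.0], [s, 0.0], [s / 2, s * np.sqrt(3) / 2]])
        df = delaunay_metrics(pts)
        assert np.allclose(
            df["delaunay_mean_area_um2"], np.sqrt(3) / 4 * s**2
        )
        assert np.allclose(df["delaunay_mean_dist_um"], s)

    def test_infinite_radius_reproduces_unpruned(self):
        from scipy.spatial import Delaunay

        rng = np.random.default_rng(11)
        pts = rng.uniform(0, 50_000, (200, 2))
        df = delaunay_metrics(pts, max_radius_um=np.inf)
        tri = Delaunay(pts)
        degree = np.zeros(len(pts), int)
        seen = set()
        for simplex in tri.simplices:
            for i in range(3):
                e = (min(simplex[i], simplex[(i + 1) % 3]),
                     max(simplex[i], simplex[(i + 1) % 3]))
                if e not in seen:
                    seen.add(e)
                    degree[e[0]] += 1
                    degree[e[1]] += 1
        assert np.array_equal(df["n_neighbors"].to_numpy(), degree)
        assert not df["is_fallback"].any()

    def test_collinear_points_all_fallback(self):
        pts = np.column_stack([np.arange(5) * 100.0, np.zeros(5)])
        df = delaunay_metrics(pts)
        assert df["is_fallback"].all()


class TestClusterDelaunay:
    def test_dense_cluster_no_isolated(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 4000, (50, 2))
        per_islet, summary = cluster_delaunay(pts, np.array(["I"] * 50))
        assert summary.iloc[0]["isolated_fraction"] == 0.0

    def test_three_far_islets_all_isolated(self):
        d = 10_000.0
        pts = np.array([[0.0, 0.0], [d, 0.0], [d / 2, d * np.sqrt(3) / 2]])
        per_islet, summary = cluster_delaunay(pts, np.array(["I"] * 3))
        assert summary.iloc[0]["isolated_fraction"] == 1.0

    def test_scope_ignores_other_clusters(self):
        # two interleaved clusters; cross-cluster neighbours must not count
        xs = np.arange(10) * 1000.0
        pts = np.column_stack([xs, np.zeros(10)])
        labels = np.array(["A", "B"] * 5)
        per_islet, _ = cluster_delaunay(pts, labels, max_radius_um=1500.0)
        # same-cluster spacing is 2,000 µm > 1,500 µm: everyone isolated
        assert per_islet["is_isolated"].all()
        # pooled control: only the two chain endpoints lack 2 neighbours
        pooled, _ = cluster_delaunay(pts, np.array(["A"] * 10), max_radius_um=1500.0)
        assert pooled["is_isolated"].sum() == 2

    def test_larger_radius_never_increases_isolation(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 30_000, (60, 2))
        labels = np.array(["I"] * 60)
        _, s1 = cluster_delaunay(pts, labels, max_radius_um=4000)
        _, s2 = cluster_delaunay(pts, labels, max_radius_um=8000)
        assert s2.iloc[0]["isolated_fraction"] <= s1.iloc[0]["isolated_fraction"]

    def test_tiny_cluster_suppressed(self):
        pts = np.array([[0.0, 0.0], [100.0, 0.0]])
        _, summary = cluster_delaunay(pts, np.array(["I", "I"]))
        assert bool(summary.iloc[0]["suppressed"])
        assert "<3 islets" in summary.iloc[0]["suppression_reason"]


class TestBackProject:
    def _islets(self, rows):
        return pd.DataFrame(rows)

    def test_empty_set_outline_only(self):
        doc = back_project(self._islets([]), box(0, 0, 100, 100))
        assert len(doc["features"]) == 1
        assert doc["features"][0]["properties"]["role"] == "tissue_outline"

    def test_cd45_binning_rule(self):
        assert cd45_bin_label(0) == "0"
        assert cd45_bin_label(4) == "1-4"
        assert cd45_bin_label(9) == "5-9"
        assert cd45_bin_label(14) == "10-14"
        assert cd45_bin_label(17) == "15+"

    def test_relative_radii_preserved(self):
        rows = [
            {"islet_id": 0, "centroid_x_um": 10, "centroid_y_um": 10,
             "equivalent_diameter_um": 40.0, "cluster": "I"},
            {"islet_id": 1, "centroid_x_um": 50, "centroid_y_um": 50,
             "equivalent_diameter_um": 80.0, "cluster": "II"},
        ]
        doc = back_project(self._islets(rows), box(0, 0, 100, 100), enlargement=3.0)
        r0 = doc["features"][1]["properties"]["radius_um"]
        r1 = doc["features"][2]["properties"]["radius_um"]
        assert r1 / r0 == pytest.approx(2.0)

    def test_invalid_color_mode(self):
        with pytest.raises(ValueError):
            back_project(self._islets([]), box(0, 0, 1, 1), color_by="bogus")
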