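import dataclasses

import numpy as np
import pandas as pd
import pytest
import shapely
from scipy import ndimage

from isletmap.core import CHANNELS_9, DEFINING_6
from isletmap.synth import (
    CD45Model,
    StageTemplate,
    channel_layout,
    generate_cells,
    generate_islets,
    generate_tissue,
    load_template,
    render_stain_masks,
    union_fractions,
)

from .conftest import template_with_idi


def shoelace_area(coords) -> float:
    """Independent polygon-area oracle."""
    c = np.asarray(coords)
    x, y = c[:, 0], c[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


class TestGenerateTissue:
    def test_zero_irregularity_is_exact_rectangle(self):
        t = generate_tissue(1, 20, 20, 0.0)
        assert t.parenchymal_area_mm2 == pytest.approx(400.0)
        assert t.boundary.bounds == (0.0, 0.0, 20000.0, 20000.0)

    def test_deterministic_for_fixed_seed(self):
        a = generate_tissue(1, 20, 20, 0.3)
        b = generate_tissue(1, 20, 20, 0.3)
        assert a.boundary.equals_exact(b.boundary, 0)

    def test_area_within_bounds_shoelace_oracle(self):
        t = generate_tissue(2, 20, 20, 0.3)
        area = shoelace_area(t.boundary.exterior.coords)
        assert 0.5 * 400e6 <= area <= 1.0 * 400e6
        assert area == pytest.approx(t.boundary.area)

    def test_simple_polygon_in_bbox(self):
        for seed in range(5):
            t = generate_tissue(seed, 10, 6, 0.5)
            assert t.boundary.is_valid
            x0, y0, x1, y1 = t.boundary.bounds
            assert x0 >= -1e-9 and y0 >= -1e-9
            assert x1 <= 10000 + 1e-9 and y1 <= 6000 + 1e-9

    @pytest.mark.parametrize("w,h", [(0, 10), (10, -1)])
    def test_invalid_dimensions(self, w, h):
        with pytest.raises(ValueError):
            generate_tissue(1, w, h, 0.1)


class TestTemplates:
    def test_builtin_presets_all_load(self):
        for stage in ("Ctrl", "AAb", "T1DS", "T1DL"):
            for region in ("PT", "PH"):
                t = load_template(f"{stage}_{region}")
                assert t.stage_label == stage and t.region == region

    def test_weights_must_sum_to_one(self, ctrl_pt_template):
        bad = dict(ctrl_pt_template.cluster_weights)
        bad["I"] += 0.2
        with pytest.raises(ValueError, match="sum"):
            dataclasses.replace(ctrl_pt_template, cluster_weights=bad)

    def test_idi_consistency_enforced(self, ctrl_pt_template):
        with pytest.raises(ValueError, match="frac_IDI"):
            dataclasses.replace(ctrl_pt_template, frac_IDI=0.9)

    def test_roundtrip_through_dict(self, ctrl_pt_template):
        d = ctrl_pt_template.to_dict()
        assert StageTemplate.from_dict(d).to_dict() == d


class TestGenerateIslets:
    def test_zero_density_empty_table(self, ctrl_pt_template, square_tissue):
        t = dataclasses.replace(ctrl_pt_template, islet_density_per_mm2=0.0)
        islets, truth = generate_islets(t, square_tissue, seed=1)
        assert len(islets) == 0 and len(truth) == 0
        assert "polygon_wkt" in islets.columns

    def test_deterministic_byte_identical(self, ctrl_pt_template, square_tissue):
        a, ta = generate_islets(ctrl_pt_template, square_tissue, seed=3)
        b, tb = generate_islets(ctrl_pt_template, square_tissue, seed=3)
        assert a.to_csv(index=False) == b.to_csv(index=False)
        assert ta.to_csv(index=False) == tb.to_csv(index=False)

    def test_idi_fraction_within_3se(self, ctrl_pt_template):
        template = template_with_idi(0.01, ctrl_pt_template)
        template = dataclasses.replace(template, islet_density_per_mm2=2.0)
        tissue = generate_tissue(0, 32, 32, 0.0)
        islets, truth = generate_islets(template, tissue, seed=7)
        n = len(islets)
        assert n > 1500
        se = np.sqrt(0.01 * 0.99 / n)
        assert abs(truth["is_IDI"].mean() - 0.01) <= 3 * se

    def test_geometry_inside_tissue_and_min_area(self, ctrl_pt_template, square_tissue):
        islets, _ = generate_islets(ctrl_pt_template, square_tissue, seed=5)
        assert len(islets) > 0
        for wkt in islets["polygon_wkt"]:
            poly = shapely.from_wkt(wkt)
            assert square_tissue.boundary.contains(poly)
            assert poly.area >= 1000.0

    def test_islets_pairwise_disjoint(self, ctrl_pt_template, square_tissue):
        islets, _ = generate_islets(ctrl_pt_template, square_tissue, seed=5)
        polys = [shapely.from_wkt(w) for w in islets["polygon_wkt"]]
        tree = shapely.STRtree(polys)
        for i, p in enumerate(polys):
            for j in tree.query(p, predicate="intersects"):
                if int(j) != i:
                    assert p.intersection(polys[int(j)]).area == 0.0

    def test_poisson_count_scale(self, ctrl_pt_template):
        tissue = generate_tissue(0, 20, 20, 0.0)
        islets, _ = generate_islets(ctrl_pt_template, tissue, seed=2)
        expect = ctrl_pt_template.islet_density_per_mm2 * 400
        assert abs(len(islets) - expect) < 5 * np.sqrt(expect)

    def test_lognormal_median_recovery(self, ctrl_pt_template):
        # mild truncation so the closed-form median exp(mu) applies
        template = dataclasses.replace(
            ctrl_pt_template,
            size_log_mu=float(np.log(8000.0)),
            size_log_sigma=0.8,
            islet_density_per_mm2=1.2,
        )
        tissue = generate_tissue(0, 45, 45, 0.0)
        islets, _ = generate_islets(template, tissue, seed=9)
        assert len(islets) >= 2000
        assert islets["area_um2"].median() == pytest.approx(8000.0, rel=0.05)

    def test_tissue_too_small_rejected(self, ctrl_pt_template):
        tiny = generate_tissue(0, 0.5, 0.5, 0.0)
        with pytest.raises(ValueError, match="1 mm"):
            generate_islets(ctrl_pt_template, tiny, seed=1)


class TestChannelLayout:
    def test_measures_match_fractions(self):
        fr = {"CHGA": 0.8, "ProINS_total": 0.5, "ProINS_hi": 0.2, "INS": 0.3,
              "IAPP": 0.25, "ProGCG": 0.2, "GCG": 0.1, "SST": 0.08, "PPY": 0.02}
        layout = channel_layout(fr)
        for ch, frac in fr.items():
            measured = sum(e - s for s, e in layout[ch])
            assert measured == pytest.approx(frac, abs=1e-9)

    def test_defining_union_covers_islet(self):
        fr = {"CHGA": 0.8, "ProINS_total": 0.5, "ProINS_hi": 0.2, "INS": 0.3,
              "IAPP": 0.25, "ProGCG": 0.2, "GCG": 0.1, "SST": 0.08, "PPY": 0.02}
        defining, endocrine = union_fractions(channel_layout(fr))
        assert defining == pytest.approx(1.0, abs=1e-9)
        assert endocrine <= 1.0 + 1e-9


class TestRenderStainMasks:
    def _single_islet_table(self, area=10_000.0, fractions=None):
        from .conftest import circle_polygon

        r = np.sqrt(area / np.pi)
        poly = circle_polygon(200, 200, r)
        scale = np.sqrt(area / poly.area)
        poly = shapely.affinity.scale(poly, scale, scale, origin=(200, 200))
        fr = {ch: 0.0 for ch in CHANNELS_9}
        fr.update({"CHGA": 1.0})
        if fractions:
            fr.update(fractions)
        row = {
            "islet_id": 0,
            "centroid_x_um": 200.0,
            "centroid_y_um": 200.0,
            "area_um2": poly.area,
            "polygon_wkt": poly.wkt,
        }
        row.update({f"frac_{ch}": v for ch, v in fr.items()})
        return pd.DataFrame([row])

    def test_pixel_count_matches_area(self):
        table = self._single_islet_table(area=10_000.0)
        masks = render_stain_masks(table, 1.0)
        union = np.zeros_like(masks["CHGA"].data)
        for ch in DEFINING_6:
            union |= masks[ch].data
        assert 9_000 <= union.sum() <= 11_000

    def test_zero_fraction_channel_is_empty(self):
        table = self._single_islet_table(fractions={"PPY": 0.0})
        masks = render_stain_masks(table, 1.0)
        assert masks["PPY"].data.sum() == 0

    def test_channel_fraction_within_10pct(self):
        table = self._single_islet_table(
            fractions={"CHGA": 0.8, "ProINS_total": 0.5, "INS": 0.3, "GCG": 0.2}
        )
        masks = render_stain_masks(table, 1.0)
        npix = None
        union = np.zeros_like(masks["CHGA"].data)
        for ch in DEFINING_6:
            union |= masks[ch].data
        npix = union.sum()
        for ch, frac in [("ProINS_total", 0.5), ("INS", 0.3), ("GCG", 0.2)]:
            assert masks[ch].data.sum() == pytest.approx(frac * npix, rel=0.1)

    def test_close_islets_not_merged(self):
        from .conftest import circle_polygon

        rows = []
        for i, cx in enumerate([100.0, 100.0 + 2 * 40 + 45]):  # 45 µm gap
            poly = circle_polygon(cx, 100, 40)
            row = {"islet_id": i, "centroid_x_um": cx, "centroid_y_um": 100.0,
                   "area_um2": poly.area, "polygon_wkt": poly.wkt}
            row.update({f"frac_{ch}": (1.0 if ch == "CHGA" else 0.0) for ch in CHANNELS_9})
            rows.append(row)
        masks = render_stain_masks(pd.DataFrame(rows), 2.0)
        _, n = ndimage.label(masks["CHGA"].data, structure=np.ones((3, 3)))
        assert n == 2

    def test_coarse_pixels_rejected(self):
        table = self._single_islet_table()
        with pytest.raises(ValueError, match="pixel"):
            render_stain_masks(table, 6.0)

    def test_nested_proins_hi(self):
        table = self._single_islet_table(
            fractions={"ProINS_total": 0.5, "ProINS_hi": 0.2}
        )
        masks = render_stain_masks(table, 1.0)
        hi, total = masks["ProINS_hi"].data, masks["ProINS_total"].data
        assert not (hi & ~total).any()


class TestGenerateCells:
    def test_no_cd45_when_prevalence_zero(self, ctrl_pt_template, square_tissue):
        template = dataclasses.replace(
            ctrl_pt_template, cd45_model=CD45Model(p_any_cd45=0.0, p_insulitic=0.0)
        )
        islets, truth = generate_islets(template, square_tissue, seed=1)
        cells, _ = generate_cells(islets, truth, template, seed=2)
        assert (cells["class"] == "CD45").sum() == 0

    def test_deterministic(self, ctrl_pt_template, square_tissue):
        islets, truth = generate_islets(ctrl_pt_template, square_tissue, seed=1)
        a, _ = generate_cells(islets, truth, ctrl_pt_template, seed=5)
        b, _ = generate_cells(islets, truth, ctrl_pt_template, seed=5)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_truth_counts_partition(self, ctrl_pt_template, square_tissue):
        islets, truth = generate_islets(ctrl_pt_template, square_tissue, seed=4)
        cells, cell_truth = generate_cells(islets, truth, ctrl_pt_template, seed=6)
        total = (cells["class"] == "CD45").sum()
        assert total == cell_truth["cd45_intra_true"].sum() + cell_truth["cd45_peri_true"].sum()
        assert total == truth["cd45_total"].sum()

    def test_empty_table_allowed(self, ctrl_pt_template, square_tissue):
        t = dataclasses.replace(ctrl_pt_template, islet_density_per_mm2=0.0)
        islets, truth = generate_islets(t, square_tissue, seed=1)
        cells, cell_truth = generate_cells(islets, truth, t, seed=1)
        assert len(cells) == 0 and len(cell_truth) == 0


class TestStatisticRecovery:
    def test_subset_fractions_recovered_downstream(self, ctrl_pt_template):
        """Generator-configured fractions recovered by classification
        within 3 binomial SE on n >= 1,000 islets."""
        from isletmap.core import CHANNELS_9 as CH
        from isletmap.hormones import HormoneProfile, classify_subsets

        template = dataclasses.replace(ctrl_pt_template, islet_density_per_mm2=2.0)
        tissue = generate_tissue(0, 26, 26, 0.0)
        islets, truth = generate_islets(template, tissue, seed=11)
        n = len(islets)
        assert n >= 1000

        flags = [
            classify_subsets(
                HormoneProfile(
                    islet_id=int(r["islet_id"]),
                    fraction_of_islet={c: float(r[f"frac_{c}"]) for c in CH},
                )
            )
            for _, r in islets.iterrows()
        ]

        def within_3se(observed, p):
            se = np.sqrt(max(p * (1 - p), 1e-9) / n)
            return abs(observed - p) <= 3 * se + 1e-12

        assert within_3se(np.mean([f.is_IDI for f in flags]), template.frac_IDI)
        assert within_3se(
            np.mean([f.is_GCG_deficient for f in flags]), template.frac_GCG_deficient
        )
        ppy_dom = np.mean([f.is_IDI and f.is_PPY_positive for f in flags])
        assert within_3se(ppy_dom, template.frac_PPY_dominant)
        assert within_3se(
            (truth["cd45_total"] >= 1).mean(), template.cd45_model.p_any_cd45
        )
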