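import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from shapely.geometry import Polygon, box

from isletmap.core import StainMask, TissueSection
from isletmap.synth import CD45Model, StageTemplate, load_template

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ctrl_pt_template() -> StageTemplate:
    return load_template("Ctrl_PT")


@pytest.fixture
def square_tissue() -> TissueSection:
    """4 x 4 mm square tissue section."""
    return TissueSection(boundary=box(0, 0, 4000, 4000))


def make_mask(data, pixel_size_um=1.0, channel="CHGA") -> StainMask:
    return StainMask(data=np.asarray(data, bool), pixel_size_um=pixel_size_um, channel=channel)


def circle_polygon(cx, cy, radius, n=256) -> Polygon:
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Polygon(
        np.column_stack([cx + radius * np.cos(theta), cy + radius * np.sin(theta)])
    )


def template_with_idi(frac_idi: float, base: StageTemplate) -> StageTemplate:
    """Rebalance cluster weights so IDI clusters sum to ``frac_idi``."""
    w = dict(base.cluster_weights)
    idi = {"IV": 0.3 * frac_idi, "V-A": 0.3 * frac_idi, "V-BC": 0.4 * frac_idi}
    beta_total = 1.0 - frac_idi
    beta_now = w["I"] + w["II"] + w["III"]
    scale = beta_total / beta_now
    weights = {
        "I": w["I"] * scale,
        "II": w["II"] * scale,
        "III": w["III"] * scale,
        **idi,
    }
    return dataclasses.replace(
        base,
        frac_IDI=frac_idi,
        frac_PPY_dominant=idi["IV"],
        frac_GCG_deficient=max(base.frac_GCG_deficient, idi["IV"] + weights["III"]),
        cluster_weights=weights,
    )


#: Hormone rules giving six well-separated clusters (used by the
#: clustering-recovery tests).
SEPARATED_RULES = {
    "I": {"CHGA": 0.90, "ProINS_total": 0.60, "ProINS_hi": 0.20, "INS": 0.40,
          "IAPP": 0.35, "ProGCG": 0.25, "GCG": 0.15, "SST": 0.05, "PPY": 0.004},
    "II": {"CHGA": 0.70, "ProINS_total": 0.30, "ProINS_hi": 0.10, "INS": 0.20,
           "IAPP": 0.15, "ProGCG": 0.18, "GCG": 0.10, "SST": 0.25, "PPY": 0.004},
    "III": {"CHGA": 0.60, "ProINS_total": 0.45, "ProINS_hi": 0.15, "INS": 0.30,
            "IAPP": 0.25, "ProGCG": 0.004, "GCG": 0.004, "SST": 0.08, "PPY": 0.35},
    "IV": {"CHGA": 0.30, "ProINS_total": 0.004, "ProINS_hi": 0.002, "INS": 0.004,
           "IAPP": 0.004, "ProGCG": 0.004, "GCG": 0.004, "SST": 0.06, "PPY": 0.85},
    "V-A": {"CHGA": 0.85, "ProINS_total": 0.004, "ProINS_hi": 0.002, "INS": 0.004,
            "IAPP": 0.004, "ProGCG": 0.60, "GCG": 0.30, "SST": 0.05, "PPY": 0.004},
    "V-BC": {"CHGA": 0.55, "ProINS_total": 0.004, "ProINS_hi": 0.002, "INS": 0.004,
             "IAPP": 0.004, "ProGCG": 0.35, "GCG": 0.18, "SST": 0.30, "PPY": 0.004},
}


def separated_template(base: StageTemplate) -> StageTemplate:
    """Well-separated six-cluster template for label-recovery tests."""
    return dataclasses.replace(
        base,
        islet_density_per_mm2=2.0,
        hormone_rules={c: dict(v) for c, v in SEPARATED_RULES.items()},
        cluster_weights={"I": 0.15, "II": 0.15, "III": 0.15, "IV": 0.2,
                         "V-A": 0.15, "V-BC": 0.2},
        frac_IDI=0.55,
        frac_PPY_dominant=0.2,
        frac_GCG_deficient=0.35,
        cd45_model=CD45Model(
            p_any_cd45=0.30, nb_mean=8.0, nb_dispersion=6.0, p_insulitic=0.01
        ),
        spatial_mode="uniform",
    )
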