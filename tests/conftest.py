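import math

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from keapsense import (
    ActivityEstimate,
    CalibrationPoint,
    REPORTED_SENSOR_VARIANTS,
    parse_protein_variant,
)


@pytest.fixture
def power_law_points():
    """Noiseless calibration series on mrna = (100/level)^1 at the graded levels."""
    return [
        CalibrationPoint(keap1_level=lv, mrna_rel=100.0 / lv, replicate_id=f"r{lv:g}")
        for lv in (100.0, 40.0, 19.0, 5.0)
    ]


@pytest.fixture
def anchor_points():
    """Replicated anchor pairs (100%, 1.0-fold) and (26%, 4.0-fold) plus a
    midpoint on the same power law, giving three distinct levels."""
    slope = math.log(4.0) / math.log(26.0 / 100.0)  # two-point slope, ~ -1.0291
    pts = []
    for lv, m in ((100.0, 1.0), (26.0, 4.0)):
        for r in range(3):
            pts.append(CalibrationPoint(keap1_level=lv, mrna_rel=m, replicate_id=f"{lv:g}_{r}"))
    mid = 51.0
    pts.append(
        CalibrationPoint(
            keap1_level=mid, mrna_rel=(mid / 100.0) ** slope, replicate_id="mid"
        )
    )
    return pts


@pytest.fixture
def reported_variants():
    """The seven human sensor-region variants from the population panels."""
    return [parse_protein_variant(t) for t in REPORTED_SENSOR_VARIANTS]


def make_estimate(point, half_width, **kw):
    return ActivityEstimate(
        activity_point=point,
        ci_low=point - half_width,
        ci_high=point + half_width,
        **kw,
    )
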