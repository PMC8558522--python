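import datetime

import numpy as np
import pytest

from gaber.geometry import SegmentedVisit, rasterize_disk
from gaber.registration import EyePair

BASE_DATE = datetime.date(2020, 1, 1)
YEAR_LATER = datetime.date(2020, 12, 31)  # 365 days
IDENTITY = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])


def landmarks_for(shape):
    r, c = shape
    return np.array([[0.1 * r, 0.1 * c], [0.1 * r, 0.9 * c], [0.9 * r, 0.2 * c]])


def visit_from_mask(
    mask,
    pixel_size_mm=0.01,
    fovea_px=None,
    laterality="OD",
    date=BASE_DATE,
):
    mask = np.asarray(mask, dtype=bool)
    if fovea_px is None:
        fovea_px = ((mask.shape[0] - 1) / 2.0, (mask.shape[1] - 1) / 2.0)
    return SegmentedVisit(
        mask=mask,
        fovea_px=fovea_px,
        landmarks_px=landmarks_for(mask.shape),
        visit_date=date,
        laterality=laterality,
        pixel_size_mm=pixel_size_mm,
    )


def pair_from_masks(base_mask, follow_mask, pixel_size_mm=0.01,
                    interval_years=1.0, fovea_px=None):
    baseline = visit_from_mask(base_mask, pixel_size_mm, fovea_px)
    followup = visit_from_mask(follow_mask, pixel_size_mm, fovea_px,
                               date=YEAR_LATER)
    return EyePair(
        baseline=baseline,
        followup=followup,
        interval_years=interval_years,
        transform=IDENTITY.copy(),
        patient_id="P0",
        eye_id="P0-OD",
    )


def fovea_centered_disk_visit(radius_mm, shape=(300, 300), pixel_size_mm=0.01,
                              **kwargs):
    fovea = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    mask = rasterize_disk(shape, fovea, radius_mm, pixel_size_mm)
    return visit_from_mask(mask, pixel_size_mm, fovea, **kwargs)


@pytest.fixture
def concentric_disk_pair():
    """Fovea-centered disks growing 1.0 -> 1.2 mm over one year at 10 um."""
    shape = (300, 300)
    fovea = (149.5, 149.5)
    base = rasterize_disk(shape, fovea, 1.0, 0.01)
    follow = rasterize_disk(shape, fovea, 1.2, 0.01)
    return pair_from_masks(base, follow, fovea_px=fovea)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
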