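"""Landmark-based registration of serial visits.

The follow-up visit is mapped into the baseline visit's pixel frame
with the unique affine transform determined by three corresponding
vessel-bifurcation landmarks (an exact 6-degree-of-freedom solve, not a
least-squares fit: three non-collinear point pairs fully determine an
affine map).  Masks are resampled with nearest-neighbor interpolation
so they stay binary; the fovea used downstream is the baseline one.
"""

from __future__ import annotations

import dataclasses
import datetime

import numpy as np
from scipy import ndimage

from .geometry import SegmentedVisit

#: Minimum landmark-triangle area (px²) below which the triplet is
#: considered degenerate.
MIN_TRIANGLE_AREA_PX2 = 1e-6

DAYS_PER_YEAR = 365.25


@dataclasses.dataclass
class EyePair:
    """A registered baseline/follow-up visit pair for one eye.

    ``followup`` has been resampled into the baseline pixel frame;
    ``transform`` is the 2x3 affine (row, col convention) that maps
    original follow-up pixel coordinates onto baseline coordinates.
    """

    baseline: SegmentedVisit
    followup: SegmentedVisit
    interval_years: float
    transform: np.ndarray
    patient_id: str = ""
    eye_id: str = ""

    def __post_init__(self) -> None:
        if self.interval_years <= 0:
            raise ValueError("interval_years must be positive")
        self.transform = np.asarray(self.transform, dtype=float)
        if self.transform.shape != (2, 3):
            raise ValueError("transform must be a 2x3 affine matrix")


def _triangle_area(points: np.ndarray) -> float:
    a, b, c = np.asarray(points, dtype=float)
    u, v = b - a, c - a
    return 0.5 * abs(u[0] * v[1] - u[1] * v[0])


def fit_landmark_transform(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Exact affine transform sending each ``src`` point to ``dst``.

    Both arguments are (3, 2) arrays of (row, col) points; the i-th
    points correspond.  Raises if either triplet is collinear.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != (3, 2) or dst.shape != (3, 2):
        raise ValueError("src and dst must each be three (row, col) points")
    for name, pts in (("src", src), ("dst", dst)):
        if _triangle_area(pts) < MIN_TRIANGLE_AREA_PX2:
            raise ValueError(
                f"{name} landmarks are collinear or coincident: {pts.tolist()}"
            )
    homo = np.column_stack([src, np.ones(3)])  # (3, 3)
    # Solve homo @ params.T = dst for each output coordinate.
    params = np.linalg.solve(homo, dst)  # (3, 2): rows are [a, b; c, d; tr, tc]
    transform = np.zeros((2, 3))
    transform[:, :2] = params[:2].T
    transform[:, 2] = params[2]
    return transform


def apply_transform(transform: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Apply a 2x3 affine to (N, 2) points (row, col)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    return points @ transform[:, :2].T + transform[:, 2]


def invert_transform(transform: np.ndarray) -> np.ndarray:
    """Inverse of a 2x3 affine transform."""
    linear = transform[:, :2]
    inv_linear = np.linalg.inv(linear)
    inverse = np.zeros((2, 3))
    inverse[:, :2] = inv_linear
    inverse[:, 2] = -inv_linear @ transform[:, 2]
    return inverse


def resample_mask(
    visit: SegmentedVisit,
    transform: np.ndarray,
    output_shape: tuple[int, int] | None = None,
) -> SegmentedVisit:
    """Warp a visit into the target frame defined by ``transform``.

    The mask is resampled with nearest-neighbor interpolation (order 0)
    so that it stays strictly binary; the fovea and landmarks are mapped
    with the same affine.  Raises if a non-empty lesion ends up entirely
    outside the output frame.
    """
    output_shape = output_shape or visit.shape
    inverse = invert_transform(np.asarray(transform, dtype=float))
    warped = ndimage.affine_transform(
        visit.mask.astype(np.uint8),
        matrix=inverse[:, :2],
        offset=inverse[:, 2],
        output_shape=output_shape,
        order=0,
        mode="constant",
        cval=0,
    ).astype(bool)
    if visit.mask.any() and not warped.any():
        raise ValueError("transform maps the lesion entirely outside the frame")
    fovea = apply_transform(transform, np.array([visit.fovea_px]))[0]
    landmarks = apply_transform(transform, visit.landmarks_px)
    return SegmentedVisit(
        mask=warped,
        fovea_px=(fovea[0], fovea[1]),
        landmarks_px=landmarks,
        visit_date=visit.visit_date,
        laterality=visit.laterality,
        pixel_size_mm=visit.pixel_size_mm,
    )


def annualize(baseline_date: datetime.date, followup_date: datetime.date) -> float:
    """Interval between two visit dates in years (365.25-day years)."""
    days = (followup_date - baseline_date).days
    if days <= 0:
        raise ValueError(
            f"follow-up date {followup_date} is not after baseline {baseline_date}"
        )
    return days / DAYS_PER_YEAR


def register_pair(
    baseline: SegmentedVisit,
    followup: SegmentedVisit,
    patient_id: str = "",
    eye_id: str = "",
) -> EyePair:
    """Register a follow-up visit onto its baseline and build an EyePair.

    The transform is fitted from the ordered landmark triplets
    (follow-up → baseline) and the follow-up mask resampled into the
    baseline frame.  The visit interval is annualized from the dates.
    """
    if baseline.laterality != followup.laterality:
        raise ValueError("visits of one eye must share laterality")
    transform = fit_landmark_transform(followup.landmarks_px, baseline.landmarks_px)
    warped = resample_mask(followup, transform, output_shape=baseline.shape)
    interval = annualize(baseline.visit_date, followup.visit_date)
    return EyePair(
        baseline=baseline,
        followup=warped,
        interval_years=interval,
        transform=transform,
        patient_id=patient_id,
        eye_id=eye_id,
    )
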