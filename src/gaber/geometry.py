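"""Mask geometry and per-visit lesion morphometrics.

A segmented visit is a binary raster in which ``True`` marks atrophic
retina, together with the physical metadata needed to interpret it: the
pixel size (default 10 µm), the continuous pixel coordinates of the
foveal center, three vessel-bifurcation landmarks used for registration,
the visit date, and the eye's laterality (OD = right, OS = left).

Physical coordinates are expressed in millimetres relative to the fovea
with +x pointing temporally (which direction that is on the raster
depends on laterality) and +y pointing superiorly (up the image, i.e.
decreasing row index).  Rows and columns are 0-based and refer to pixel
centers.

Connectivity conventions: lesions are connected components under
8-connectivity; border pixels are lesion pixels with at least one
non-lesion 4-neighbor.  Pixels outside the frame count as non-lesion,
so a lesion touching the frame edge contributes border pixels there
(such masks are logged, since the imaging field has cut the lesion).
"""

from __future__ import annotations

import dataclasses
import datetime
import logging

import numpy as np
from scipy import ndimage
from skimage import measure

logger = logging.getLogger(__name__)

#: 3x3 structuring element for lesion components (8-connectivity).
COMPONENT_STRUCTURE = np.ones((3, 3), dtype=bool)

#: Cross-shaped element for border detection (4-neighborhood).
BORDER_STRUCTURE = ndimage.generate_binary_structure(2, 1)

LATERALITIES = ("OD", "OS")


def _as_binary(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    if mask.dtype != bool:
        values = np.unique(mask)
        if not np.isin(values, (0, 1, 255)).all():
            raise ValueError(
                "mask is not binary: values other than {0, 1, 255} present"
            )
        mask = mask > 0
    return mask


@dataclasses.dataclass
class SegmentedVisit:
    """One visit's lesion segmentation plus spatial metadata.

    Parameters
    ----------
    mask:
        2-D boolean raster, ``True`` on atrophic pixels.
    fovea_px:
        (row, col) continuous pixel coordinates of the foveal center.
    landmarks_px:
        Three (row, col) points at vessel bifurcations, ordered; the
        order defines correspondence across visits.
    visit_date:
        Calendar date of the visit.
    laterality:
        ``"OD"`` (right eye) or ``"OS"`` (left eye).
    pixel_size_mm:
        Physical width of one pixel in mm (default 0.01, i.e. 10 µm).
    """

    mask: np.ndarray
    fovea_px: tuple[float, float]
    landmarks_px: np.ndarray
    visit_date: datetime.date
    laterality: str
    pixel_size_mm: float = 0.01

    def __post_init__(self) -> None:
        self.mask = _as_binary(self.mask)
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")
        if self.laterality not in LATERALITIES:
            raise ValueError(f"laterality must be one of {LATERALITIES}")
        self.fovea_px = (float(self.fovea_px[0]), float(self.fovea_px[1]))
        self.landmarks_px = np.asarray(self.landmarks_px, dtype=float)
        if self.landmarks_px.shape != (3, 2):
            raise ValueError("landmarks_px must be three (row, col) points")
        if _touches_frame(self.mask):
            logger.info(
                "lesion touches the imaging frame; border statistics near "
                "the frame edge reflect the field of view, not the lesion"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclasses.dataclass(frozen=True)
class MorphometricsRecord:
    """Per-visit lesion morphometrics."""

    area_mm2: float
    perimeter_mm: float
    lesion_count: int
    circularity: float
    mean_border_fovea_dist_mm: float


@dataclasses.dataclass(frozen=True)
class BorderPointSet:
    """Lesion border pixels with fovea-relative polar coordinates."""

    points_px: np.ndarray  # (N, 2) int rows/cols
    eccentricity_mm: np.ndarray  # (N,)
    angle_deg: np.ndarray  # (N,) in [0, 360), 0 = temporal, 90 = superior

    def __len__(self) -> int:
        return len(self.points_px)


def _touches_frame(mask: np.ndarray) -> bool:
    return bool(
        mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any()
    )


def lesion_count(visit: SegmentedVisit) -> int:
    """Number of disjoint lesions (8-connected components); 0 if empty."""
    _, n = ndimage.label(visit.mask, structure=COMPONENT_STRUCTURE)
    return int(n)


def area_mm2(visit: SegmentedVisit) -> float:
    """Total lesion area: pixel count times the pixel area."""
    return float(visit.mask.sum()) * visit.pixel_size_mm**2


#: Gaussian pre-smoothing (px) applied before iso-contouring; damps the
#: staircase bias of marching squares on raw binary rasters (~5% high on
#: a disk) to below 1% without visibly rounding corners at 10 µm pixels.
PERIMETER_SMOOTHING_SIGMA_PX = 1.0


def _contour_length_px(field: np.ndarray, level: float = 0.5) -> float:
    total = 0.0
    for contour in measure.find_contours(field, level):
        total += float(np.linalg.norm(np.diff(contour, axis=0), axis=1).sum())
    return total


def perimeter_mm(visit: SegmentedVisit) -> float:
    """Total lesion perimeter from sub-pixel iso-contours.

    Each 8-connected lesion is lightly smoothed and contoured at level
    0.5 (marching squares); polyline lengths are summed over all outer
    and hole contours.  Sub-pixel contouring avoids the systematic
    ~27% overestimate that boundary-pixel counting produces on smooth
    shapes, which matters because the circularity index and the
    perimeter-adjusted growth rate divide by perimeter.  Components too
    small to survive smoothing are contoured on the raw binary raster.
    """
    if not visit.mask.any():
        return 0.0
    labels, n = ndimage.label(visit.mask, structure=COMPONENT_STRUCTURE)
    total_px = 0.0
    for sl, label in zip(ndimage.find_objects(labels), range(1, n + 1)):
        component = np.pad(labels[sl] == label, 4)
        smoothed = ndimage.gaussian_filter(
            component.astype(float), PERIMETER_SMOOTHING_SIGMA_PX
        )
        length = _contour_length_px(smoothed)
        if length == 0.0:  # component vanished under smoothing
            length = _contour_length_px(np.pad(component, 1).astype(float))
        total_px += length
    return total_px * visit.pixel_size_mm


def circularity(area_mm2: float, perimeter_mm: float) -> float:
    """Circularity index 4·pi·area / perimeter².

    Equals 1 for a circle and approaches 0 for elongated or multifocal
    lesions.  Rasterized convex lesions may exceed 1 by a small
    discretization tolerance; the value is not clipped.
    """
    if perimeter_mm <= 0:
        raise ValueError("perimeter is zero: no lesion to characterize")
    return float(4.0 * np.pi * area_mm2 / perimeter_mm**2)


def border_mask(mask: np.ndarray) -> np.ndarray:
    """Boolean raster of lesion pixels with a non-lesion 4-neighbor.

    Out-of-frame pixels count as non-lesion, so lesion pixels on the
    frame edge are border pixels.
    """
    mask = _as_binary(mask)
    interior = ndimage.binary_erosion(
        mask, structure=BORDER_STRUCTURE, border_value=0
    )
    return mask & ~interior


def physical_xy(
    points_px: np.ndarray,
    fovea_px: tuple[float, float],
    pixel_size_mm: float,
    laterality: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Convert (row, col) pixel points to fovea-relative (x, y) in mm.

    +x is temporal, +y is superior.  On the raster, superior is up
    (decreasing row).  Temporal is toward decreasing column for OD and
    increasing column for OS (the optic disc, which is nasal, sits on
    the opposite side).
    """
    points_px = np.atleast_2d(np.asarray(points_px, dtype=float))
    y = (fovea_px[0] - points_px[:, 0]) * pixel_size_mm
    dx = (points_px[:, 1] - fovea_px[1]) * pixel_size_mm
    x = -dx if laterality == "OD" else dx
    return x, y


def polar_about_fovea(
    points_px: np.ndarray,
    fovea_px: tuple[float, float],
    pixel_size_mm: float,
    laterality: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Eccentricity (mm) and polar angle (deg) of pixel points.

    Angle is measured counter-clockwise from the temporal direction,
    so 0° = temporal, 90° = superior, 180° = nasal, 270° = inferior.
    """
    x, y = physical_xy(points_px, fovea_px, pixel_size_mm, laterality)
    ecc = np.hypot(x, y)
    angle = np.degrees(np.arctan2(y, x)) % 360.0
    return ecc, angle


def extract_border(visit: SegmentedVisit) -> BorderPointSet:
    """All border pixels of a visit with eccentricity and angle."""
    if not visit.mask.any():
        raise ValueError("cannot extract a border from an empty mask")
    points = np.argwhere(border_mask(visit.mask))
    ecc, angle = polar_about_fovea(
        points, visit.fovea_px, visit.pixel_size_mm, visit.laterality
    )
    return BorderPointSet(points_px=points, eccentricity_mm=ecc, angle_deg=angle)


def mean_border_fovea_distance(pair) -> float:
    """Mean border-to-fovea distance (mm), averaged over the two visits.

    For each visit, the mean Euclidean distance from every border pixel
    to the foveal center is computed; the two per-visit means are then
    averaged.  The registered pair shares the baseline fovea.
    """
    fovea = pair.baseline.fovea_px
    per_visit = []
    for visit in (pair.baseline, pair.followup):
        if not visit.mask.any():
            raise ValueError("visit has an empty mask; no border to measure")
        points = np.argwhere(border_mask(visit.mask))
        d = np.hypot(points[:, 0] - fovea[0], points[:, 1] - fovea[1])
        per_visit.append(float(d.mean()) * visit.pixel_size_mm)
    return float(np.mean(per_visit))


def morphometrics(visit: SegmentedVisit) -> MorphometricsRecord:
    """Area, perimeter, lesion count, circularity, and mean
    border-to-fovea distance for one visit."""
    area = area_mm2(visit)
    perim = perimeter_mm(visit)
    n = lesion_count(visit)
    circ = circularity(area, perim) if perim > 0 else float("nan")
    if visit.mask.any():
        points = np.argwhere(border_mask(visit.mask))
        d = np.hypot(
            points[:, 0] - visit.fovea_px[0], points[:, 1] - visit.fovea_px[1]
        )
        border_dist = float(d.mean()) * visit.pixel_size_mm
    else:
        border_dist = float("nan")
    return MorphometricsRecord(
        area_mm2=area,
        perimeter_mm=perim,
        lesion_count=n,
        circularity=circ,
        mean_border_fovea_dist_mm=border_dist,
    )


def rasterize_disk(
    shape: tuple[int, int],
    center_px: tuple[float, float],
    radius_mm: float,
    pixel_size_mm: float = 0.01,
) -> np.ndarray:
    """Boolean disk: pixels whose center lies within ``radius_mm``."""
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    d2 = (rows - center_px[0]) ** 2 + (cols - center_px[1]) ** 2
    return d2 * pixel_size_mm**2 <= radius_mm**2


def eccentricity_grid(
    shape: tuple[int, int],
    fovea_px: tuple[float, float],
    pixel_size_mm: float,
) -> np.ndarray:
    """Per-pixel distance to the fovea in mm, for the whole frame."""
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    return (
        np.hypot(rows - fovea_px[0], cols - fovea_px[1]) * pixel_size_mm
    )
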