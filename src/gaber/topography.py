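"""Topographic zone schemes and per-zone statistics.

Three macular partitions centered on the fovea:

* ``ring_equal_width`` — seven concentric annuli with 0.5-mm radius
  increments out to 3.5 mm.
* ``ring_equal_area`` — seven concentric annuli of equal area
  pi*3.5^2/7 = 5.50 mm² each, with boundaries r_k = 3.5*sqrt(k/7).
* ``etdrs_quadrant`` — the four quadrants (temporal, superior, nasal,
  inferior) of the ETDRS grid between the 0.5-mm central circle and
  the 3-mm outer circle, split along the ±45° diagonals; the
  nasal/temporal assignment depends on laterality.

Zone intervals are half-open at the inner radius, [r_k, r_{k+1}), so a
point at exactly 0.5 mm belongs to the second ring.  Nothing beyond
3.5 mm eccentricity is assigned.  Zone denominators for the percentage
of area affected are analytic annulus/sector areas, not areas clipped
to the imaging frame; a warning is logged when the frame cuts a zone.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .ber import BorderSamples
from .geometry import eccentricity_grid, polar_about_fovea
from .registration import EyePair

logger = logging.getLogger(__name__)

MAX_ECCENTRICITY_MM = 3.5
N_RING_ZONES = 7

QUADRANT_LABELS = ("temporal", "superior", "nasal", "inferior")
ETDRS_INNER_MM = 0.5
ETDRS_OUTER_MM = 3.0

ZONE_KINDS = ("ring_equal_width", "ring_equal_area", "etdrs_quadrant")


@dataclasses.dataclass(frozen=True)
class ZoneScheme:
    """A topographic partition of the macula around the fovea."""

    kind: str
    boundaries_mm: np.ndarray
    n_zones: int
    laterality: str | None = None

    @property
    def labels(self) -> tuple[str, ...]:
        if self.kind == "etdrs_quadrant":
            return QUADRANT_LABELS
        return tuple(f"zone_{k}" for k in range(1, self.n_zones + 1))

    def zone_area_mm2(self, zone: int) -> float:
        """Analytic area of one zone (1-based index)."""
        if not 1 <= zone <= self.n_zones:
            raise ValueError(f"zone {zone} out of range 1..{self.n_zones}")
        if self.kind == "etdrs_quadrant":
            return float(np.pi * (ETDRS_OUTER_MM**2 - ETDRS_INNER_MM**2) / 4.0)
        r0, r1 = self.boundaries_mm[zone - 1], self.boundaries_mm[zone]
        return float(np.pi * (r1**2 - r0**2))

    def midpoints_mm(self) -> np.ndarray:
        """Radial midpoint of each ring (used as the eccentricity
        covariate in the zone-level mixed model)."""
        if self.kind == "etdrs_quadrant":
            raise ValueError("quadrant scheme has no radial midpoints")
        return (self.boundaries_mm[:-1] + self.boundaries_mm[1:]) / 2.0


def make_zone_scheme(kind: str, laterality: str | None = None) -> ZoneScheme:
    """Build one of the three supported zone schemes."""
    if kind == "ring_equal_width":
        boundaries = 0.5 * np.arange(N_RING_ZONES + 1)
        return ZoneScheme(kind=kind, boundaries_mm=boundaries, n_zones=N_RING_ZONES)
    if kind == "ring_equal_area":
        k = np.arange(N_RING_ZONES + 1)
        boundaries = MAX_ECCENTRICITY_MM * np.sqrt(k / N_RING_ZONES)
        return ZoneScheme(kind=kind, boundaries_mm=boundaries, n_zones=N_RING_ZONES)
    if kind == "etdrs_quadrant":
        if laterality not in ("OD", "OS"):
            raise ValueError("etdrs_quadrant scheme requires laterality OD or OS")
        boundaries = np.array([ETDRS_INNER_MM, ETDRS_OUTER_MM])
        return ZoneScheme(
            kind=kind, boundaries_mm=boundaries, n_zones=4, laterality=laterality
        )
    raise ValueError(f"unknown zone scheme kind: {kind!r}")


def assign_zones(
    eccentricity_mm: np.ndarray,
    angle_deg: np.ndarray,
    scheme: ZoneScheme,
) -> np.ndarray:
    """Vectorized zone assignment; 0 marks points outside the scheme.

    Ring zones are half-open [r_k, r_{k+1}).  Quadrants are bounded by
    the ±45° diagonals; the angle convention (0° temporal, 90°
    superior) already folds in laterality, so quadrant indices follow
    the fixed order temporal, superior, nasal, inferior.
    """
    ecc = np.asarray(eccentricity_mm, dtype=float)
    angle = np.asarray(angle_deg, dtype=float)
    zones = np.zeros(ecc.shape, dtype=int)
    if scheme.kind in ("ring_equal_width", "ring_equal_area"):
        idx = np.searchsorted(scheme.boundaries_mm, ecc, side="right")
        inside = (ecc < scheme.boundaries_mm[-1]) & (idx >= 1)
        zones[inside] = idx[inside]
        return zones
    if scheme.kind == "etdrs_quadrant":
        inside = (ecc >= ETDRS_INNER_MM) & (ecc < ETDRS_OUTER_MM)
        # Rotate so each quadrant spans a contiguous 90° bin:
        # temporal = [-45, 45), superior = [45, 135), ...
        quadrant = ((angle + 45.0) % 360.0 // 90.0).astype(int) + 1
        zones[inside] = quadrant[inside]
        return zones
    raise ValueError(f"unknown zone scheme kind: {scheme.kind!r}")


def assign_zone(
    eccentricity_mm: float, angle_deg: float, scheme: ZoneScheme
) -> int | None:
    """Scalar zone assignment; ``None`` if the point is outside."""
    zone = assign_zones(
        np.array([eccentricity_mm]), np.array([angle_deg]), scheme
    )[0]
    return int(zone) if zone > 0 else None


def zone_profile(
    pair: EyePair, samples: BorderSamples, scheme: ZoneScheme
) -> pd.DataFrame:
    """Per-zone BER and lesion-coverage statistics for one eye.

    Returns a DataFrame with one row per zone: ``zone``, ``label``,
    ``n_border_pixels``, ``mean_ber_mm_per_yr`` (NaN when the zone
    holds no border pixel — the BER is simply not defined where the
    lesion border is absent), ``ga_area_mm2`` (baseline lesion area
    inside the zone), ``zone_area_mm2`` (analytic), and
    ``pct_area_affected``.
    """
    fovea = pair.baseline.fovea_px
    shape = pair.baseline.shape
    if not (0 <= fovea[0] < shape[0] and 0 <= fovea[1] < shape[1]):
        raise ValueError("fovea lies outside the image frame")
    px = pair.baseline.pixel_size_mm
    outer_px = scheme.boundaries_mm[-1] / px
    if (
        fovea[0] - outer_px < 0
        or fovea[1] - outer_px < 0
        or fovea[0] + outer_px >= shape[0]
        or fovea[1] + outer_px >= shape[1]
    ):
        logger.warning(
            "imaging frame clips the outer zones; analytic zone areas "
            "still used as denominators"
        )

    sample_zones = assign_zones(samples.eccentricity_mm, samples.angle_deg, scheme)

    lesion_points = np.argwhere(pair.baseline.mask)
    if len(lesion_points):
        ecc, ang = polar_about_fovea(
            lesion_points, fovea, px, pair.baseline.laterality
        )
        lesion_zones = assign_zones(ecc, ang, scheme)
    else:
        lesion_zones = np.zeros(0, dtype=int)

    rows = []
    for zone in range(1, scheme.n_zones + 1):
        in_zone = sample_zones == zone
        n_px = int(in_zone.sum())
        mean_ber = (
            float(samples.local_ber_mm_per_yr[in_zone].mean()) if n_px else np.nan
        )
        mean_ecc = (
            float(samples.eccentricity_mm[in_zone].mean()) if n_px else np.nan
        )
        ga_area = float((lesion_zones == zone).sum()) * px**2
        zone_area = scheme.zone_area_mm2(zone)
        rows.append(
            {
                "zone": zone,
                "label": scheme.labels[zone - 1],
                "n_border_pixels": n_px,
                "mean_ber_mm_per_yr": mean_ber,
                "mean_eccentricity_mm": mean_ecc,
                "ga_area_mm2": ga_area,
                "zone_area_mm2": zone_area,
                "pct_area_affected": 100.0 * ga_area / zone_area,
            }
        )
    return pd.DataFrame(rows)


def pool_zone_profiles(profiles: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Pool per-eye zone profiles across a cohort.

    For each zone the mean of the eye-level zone means is reported with
    a normal-approximation 95% CI (mean ± 1.96·SE) and the number of
    contributing eyes.  Eyes without a border pixel in a zone do not
    contribute to that zone's BER.  The percentage of area affected is
    averaged over all eyes.
    """
    if not profiles:
        raise ValueError("no zone profiles to pool")
    stacked = pd.concat(profiles, keys=range(len(profiles)), names=["eye", None])
    rows = []
    for zone, group in stacked.groupby("zone"):
        bers = group["mean_ber_mm_per_yr"].dropna()
        n = len(bers)
        if n == 0:
            mean = ci_low = ci_high = np.nan
        else:
            mean = float(bers.mean())
            se = float(bers.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
            ci_low = mean - 1.96 * se if n > 1 else np.nan
            ci_high = mean + 1.96 * se if n > 1 else np.nan
        rows.append(
            {
                "zone": int(zone),
                "label": group["label"].iloc[0],
                "n_eyes": n,
                "mean_ber_mm_per_yr": mean,
                "ci_low": ci_low,
                "ci_high": ci_high,
                "mean_pct_area_affected": float(group["pct_area_affected"].mean()),
            }
        )
    return pd.DataFrame(rows)


def moving_average_trend(
    x: np.ndarray, y: np.ndarray, window: int = 3
) -> np.ndarray:
    """Centered moving-average smoother for plotted trendlines only.

    Carries no statistics; it replaces spline trendlines in figures.
    """
    y = np.asarray(y, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    pad = window // 2
    padded = np.pad(y, pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")
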