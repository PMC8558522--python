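"""Mask morphometrics: counts, areas, perimeters, borders."""

import math

import numpy as np
import pytest
from scipy import ndimage

from gaber import geometry
from gaber.geometry import (
    BORDER_STRUCTURE,
    border_mask,
    circularity,
    extract_border,
    lesion_count,
    mean_border_fovea_distance,
    perimeter_mm,
    rasterize_disk,
)

from conftest import (
    fovea_centered_disk_visit,
    pair_from_masks,
    visit_from_mask,
)


def _flood_fill_count(mask):
    """Brute-force 8-connected component count by BFS."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    count = 0
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        count += 1
        stack = [start]
        seen[start] = True
        while stack:
            r, c = stack.pop()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if (
                        0 <= rr < mask.shape[0]
                        and 0 <= cc < mask.shape[1]
                        and mask[rr, cc]
                        and not seen[rr, cc]
                    ):
                        seen[rr, cc] = True
                        stack.append((rr, cc))
    return count


class TestLesionCount:
    def test_empty_mask_has_no_lesions(self):
        # An all-background frame is valid input and counts zero lesions.
        visit = visit_from_mask(np.zeros((20, 20), bool))
        assert lesion_count(visit) == 0

    def test_disjoint_squares_counted_separately(self):
        mask = np.zeros((30, 30), bool)
        mask[2:8, 2:8] = True
        mask[15:22, 15:22] = True
        assert lesion_count(visit_from_mask(mask)) == 2

    def test_corner_touching_squares_are_one_lesion(self):
        # 8-connectivity joins squares that meet only at a corner.
        mask = np.zeros((20, 20), bool)
        mask[2:6, 2:6] = True
        mask[6:10, 6:10] = True
        assert lesion_count(visit_from_mask(mask)) == 1

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_flood_fill_oracle_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((64, 64)) < 0.35
        assert lesion_count(visit_from_mask(mask)) == _flood_fill_count(mask)


class TestAreaPerimeter:
    def test_block_area_is_pixel_count_times_pixel_area(self):
        mask = np.zeros((200, 200), bool)
        mask[40:140, 40:140] = True
        assert geometry.area_mm2(visit_from_mask(mask)) == pytest.approx(1.0)

    def test_empty_mask_has_zero_area_and_perimeter(self):
        visit = visit_from_mask(np.zeros((20, 20), bool))
        assert geometry.area_mm2(visit) == 0.0
        assert perimeter_mm(visit) == 0.0

    def test_disk_area_close_to_analytic(self):
        visit = fovea_centered_disk_visit(1.0)
        assert geometry.area_mm2(visit) == pytest.approx(math.pi, rel=0.01)

    def test_disk_perimeter_close_to_analytic(self):
        visit = fovea_centered_disk_visit(1.0)
        assert perimeter_mm(visit) == pytest.approx(2 * math.pi, rel=0.02)

    def test_square_perimeter(self):
        mask = np.zeros((200, 200), bool)
        mask[50:150, 50:150] = True  # 1 mm x 1 mm at 10 um
        assert perimeter_mm(visit_from_mask(mask)) == pytest.approx(4.0, rel=0.02)

    def test_perimeter_additive_over_disjoint_lesions(self):
        shape = (200, 400)
        one = rasterize_disk(shape, (99.5, 99.5), 0.5, 0.01)
        two = one | rasterize_disk(shape, (99.5, 299.5), 0.5, 0.01)
        p1 = perimeter_mm(visit_from_mask(one))
        p2 = perimeter_mm(visit_from_mask(two))
        assert p2 == pytest.approx(2 * p1, rel=1e-9)

    @pytest.mark.parametrize("shift", [(0, 0), (7, 3), (-5, 11)])
    def test_area_perimeter_translation_invariant(self, shift):
        base = np.zeros((120, 120), bool)
        base[40:70, 35:80] = True
        base[55:90, 60:75] = True
        moved = np.roll(np.roll(base, shift[0], axis=0), shift[1], axis=1)
        v0, v1 = visit_from_mask(base), visit_from_mask(moved)
        assert geometry.area_mm2(v0) == geometry.area_mm2(v1)
        assert perimeter_mm(v0) == pytest.approx(perimeter_mm(v1), rel=1e-9)

    def test_single_pixel_lesion_has_positive_perimeter(self):
        mask = np.zeros((20, 20), bool)
        mask[10, 10] = True
        assert perimeter_mm(visit_from_mask(mask)) > 0


class TestCircularity:
    def test_exact_circle_is_one(self):
        r = 1.0
        assert circularity(math.pi * r**2, 2 * math.pi * r) == pytest.approx(1.0)

    def test_square_is_pi_over_four(self):
        s = 2.0
        assert circularity(s**2, 4 * s) == pytest.approx(math.pi / 4)

    def test_two_identical_circles_halve_circularity(self):
        r = 1.0
        area, perim = math.pi * r**2, 2 * math.pi * r
        assert circularity(2 * area, 2 * perim) == pytest.approx(0.5)

    def test_zero_perimeter_rejected(self):
        with pytest.raises(ValueError, match="perimeter"):
            circularity(1.0, 0.0)

    @pytest.mark.parametrize("radius", [0.5, 1.5, 3.0])
    def test_rasterized_disks_near_unity(self, radius):
        shape = (int(2 * radius / 0.01) + 60,) * 2
        visit = fovea_centered_disk_visit(radius, shape=shape)
        value = circularity(geometry.area_mm2(visit), perimeter_mm(visit))
        assert 0.98 <= value <= 1.02


class TestBorder:
    def test_single_pixel_is_its_own_border(self):
        mask = np.zeros((20, 20), bool)
        mask[4, 7] = True
        border = extract_border(visit_from_mask(mask, fovea_px=(4.0, 4.0)))
        assert border.points_px.tolist() == [[4, 7]]
        assert border.eccentricity_mm[0] == pytest.approx(0.03)

    def test_three_by_three_block_has_eight_border_pixels(self):
        mask = np.zeros((9, 9), bool)
        mask[3:6, 3:6] = True
        assert len(extract_border(visit_from_mask(mask))) == 8

    def test_full_frame_mask_borders_at_frame_edge(self):
        # Out-of-frame pixels count as background, so the frame ring is
        # the border.
        mask = np.ones((10, 12), bool)
        border = border_mask(mask)
        expected = np.zeros_like(mask)
        expected[0, :] = expected[-1, :] = True
        expected[:, 0] = expected[:, -1] = True
        assert (border == expected).all()

    def test_border_pixels_are_lesion_pixels(self, rng):
        mask = ndimage.binary_closing(rng.random((64, 64)) < 0.4, iterations=2)
        assert not (border_mask(mask) & ~mask).any()

    def test_removing_border_seals_interior_from_background(self):
        visit = fovea_centered_disk_visit(0.5, shape=(140, 140))
        interior = visit.mask & ~border_mask(visit.mask)
        grown_background = ndimage.binary_dilation(
            ~visit.mask, structure=BORDER_STRUCTURE
        )
        assert not (grown_background & interior).any()

    def test_empty_mask_border_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_border(visit_from_mask(np.zeros((10, 10), bool)))


class TestBorderFoveaDistance:
    def test_fovea_centered_circle_both_visits(self):
        shape, fovea = (300, 300), (149.5, 149.5)
        mask = rasterize_disk(shape, fovea, 1.0, 0.01)
        pair = pair_from_masks(mask, mask, fovea_px=fovea)
        assert mean_border_fovea_distance(pair) == pytest.approx(1.0, abs=0.01)

    def test_growing_circle_averages_the_two_radii(self, concentric_disk_pair):
        assert mean_border_fovea_distance(concentric_disk_pair) == pytest.approx(
            1.1, abs=0.01
        )

    def test_single_pixel_at_fovea(self):
        mask = np.zeros((21, 21), bool)
        mask[10, 10] = True
        pair = pair_from_masks(mask, mask, fovea_px=(10.0, 10.0))
        assert mean_border_fovea_distance(pair) == 0.0


class TestLateralityConvention:
    def test_temporal_direction_mirrors_between_eyes(self):
        # A point toward increasing column is nasal in OD, temporal in OS.
        point = np.array([[10.0, 15.0]])
        fovea = (10.0, 10.0)
        x_od, _ = geometry.physical_xy(point, fovea, 0.01, "OD")
        x_os, _ = geometry.physical_xy(point, fovea, 0.01, "OS")
        assert x_od[0] == pytest.approx(-x_os[0])
        assert x_os[0] > 0

    def test_superior_is_up_the_image(self):
        point = np.array([[5.0, 10.0]])  # above the fovea on the raster
        _, y = geometry.physical_xy(point, (10.0, 10.0), 0.01, "OD")
        assert y[0] > 0
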