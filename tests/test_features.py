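import math

import numpy as np
import pytest

from rootquant.features import (DiameterBins, angle_features,
                                binned_histograms, branching_frequency,
                                convex_metrics, diameter_stats,
                                extent_metrics, extract_features,
                                hole_metrics, lower_root_area, network_area,
                                perimeter, row_root_counts,
                                surface_area_volume, total_length)
from rootquant.image_io import AnalysisConfig, GreyImage, RegionOfInterest
from rootquant.skeletonization import RadiusSkeleton, build_skeleton
from rootquant.topology import classify_pixels
from conftest import grey_from_array, mask_from_array, random_blob_mask

SQRT2 = math.sqrt(2.0)
PI = math.pi


def make_skel(pixels, radii=None, shape=(64, 64)):
    pixels = set(pixels)
    if radii is None:
        radii = {p: 1.0 for p in pixels}
    elif isinstance(radii, (int, float)):
        radii = {p: float(radii) for p in pixels}
    elif isinstance(radii, (list, tuple)):
        radii = dict(zip(sorted(pixels), radii))
    return RadiusSkeleton(set(pixels), radii, shape)


def hpath(n, r0=10, c0=10):
    return [(r0, c0 + i) for i in range(n)]


class TestTotalLength:
    def test_horizontal_11px_path(self):
        assert total_length(make_skel(hpath(11))) == pytest.approx(10.0)

    def test_three_px_diagonal(self):
        skel = make_skel([(5, 5), (6, 6), (7, 7)])
        assert total_length(skel) == pytest.approx(2 * SQRT2)

    def test_empty(self):
        assert total_length(make_skel([])) == 0.0


class TestDiameterStats:
    def test_mixed_radii(self):
        skel = make_skel([(1, 1), (1, 2), (1, 3)], [1.0, 2.0, 3.0])
        avg, med, mx = diameter_stats(skel)
        assert (avg, med, mx) == pytest.approx((4.0, 4.0, 6.0))

    def test_constant_radius(self):
        skel = make_skel(hpath(5), 2.0)
        assert diameter_stats(skel) == pytest.approx((4.0, 4.0, 4.0))

    def test_outlier_shifts_mean_not_median(self):
        skel = make_skel([(1, 1), (1, 2), (1, 3), (1, 4)],
                         [1.0, 1.0, 1.0, 5.0])
        avg, med, mx = diameter_stats(skel)
        assert (avg, med, mx) == pytest.approx((4.0, 2.0, 10.0))

    def test_empty_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert diameter_stats(make_skel([])) == (0.0, 0.0, 0.0)


class TestAreaPerimeter:
    def test_square_area(self):
        m = np.zeros((20, 20), bool)
        m[5:15, 5:15] = True
        assert network_area(mask_from_array(m)) == 100.0

    def test_square_perimeter_traced_contour(self):
        m = np.zeros((20, 20), bool)
        m[5:15, 5:15] = True
        # closed contour through the 36 boundary pixels, all unit steps
        assert perimeter(mask_from_array(m)) == pytest.approx(36.0)

    def test_empty(self):
        m = mask_from_array(np.zeros((5, 5)))
        assert network_area(m) == 0.0
        assert perimeter(m) == 0.0

    def test_hole_contour_counted(self):
        m = np.ones((12, 12), bool)
        m[4:8, 4:8] = False
        full = perimeter(mask_from_array(np.ones((12, 12))))
        assert perimeter(mask_from_array(m)) > full


class TestSurfaceVolume:
    def test_straight_path_closed_form(self):
        skel = make_skel(hpath(11), 2.0)
        surface, volume = surface_area_volume(skel)
        assert volume == pytest.approx(10 * PI * 4)
        assert surface == pytest.approx(10 * 2 * PI * 2)

    def test_isolated_pixel_contributes_nothing(self):
        surface, volume = surface_area_volume(make_skel([(3, 3)], 5.0))
        assert surface == 0.0 and volume == 0.0

    def test_two_wire_sum_beats_average_diameter_formula(self):
        thin = make_skel(hpath(101, r0=5), 1.0)
        thick = make_skel(hpath(101, r0=20), 5.0)
        both = make_skel(set(thin.pixels) | set(thick.pixels),
                         {**thin.radius_px, **thick.radius_px})
        _, v = surface_area_volume(both)
        assert v == pytest.approx(PI * (100 * 1 + 100 * 25))
        # additivity over the two wires
        assert v == pytest.approx(surface_area_volume(thin)[1]
                                  + surface_area_volume(thick)[1])
        # the length x average-diameter cylinder underestimates badly
        avg_r = 3.0
        v_avg = PI * avg_r ** 2 * 200
        assert v_avg < 0.75 * v


class TestBinnedHistograms:
    def test_split_at_edge(self):
        skel = make_skel([(1, 1), (1, 2), (1, 3)], [1.0, 1.0, 3.0])
        hist = binned_histograms(skel, DiameterBins((4.0,)))
        assert hist["length"].sum() == pytest.approx(total_length(skel))
        assert hist["length"][1] > 0  # the radius-3 pixel's share

    def test_single_bin_equals_totals(self):
        skel = make_skel(hpath(9), 2.0)
        hist = binned_histograms(skel, DiameterBins(()))
        surface, volume = surface_area_volume(skel)
        assert hist["length"][0] == pytest.approx(total_length(skel))
        assert hist["surface_area"][0] == pytest.approx(surface)
        assert hist["volume"][0] == pytest.approx(volume)

    def test_left_open_right_closed_boundaries(self):
        skel = make_skel([(1, 1), (1, 5), (1, 9)], [1.0, 2.0, 3.0])
        bins = DiameterBins((2.0, 4.0))
        assert bins.index(2.0) == 0   # diameter 2 falls in (0, 2]
        assert bins.index(4.0) == 1   # diameter 4 falls in (2, 4]
        assert bins.index(6.0) == 2

    def test_conservation_on_random_skeletons(self, rng):
        for _ in range(10):
            m = random_blob_mask(rng, (35, 35))
            skel = build_skeleton(mask_from_array(m))
            if not skel.pixels:
                continue
            hist = binned_histograms(skel, DiameterBins((1.5, 3.0, 4.5)))
            surface, volume = surface_area_volume(skel)
            for key, target in [("length", total_length(skel)),
                                ("surface_area", surface),
                                ("volume", volume)]:
                total = hist[key].sum()
                assert total == pytest.approx(target, rel=1e-9)


class TestBranchingFrequency:
    def test_rate(self):
        topo = classify_pixels(make_skel(
            [(10, 10), (9, 9), (8, 8), (9, 11), (8, 12), (11, 10), (12, 10)]))
        assert branching_frequency(topo, 100.0) == pytest.approx(0.01)

    def test_no_branches(self):
        topo = classify_pixels(make_skel(hpath(5)))
        assert branching_frequency(topo, 4.0) == 0.0

    def test_zero_length_warns(self):
        topo = classify_pixels(make_skel([]))
        with pytest.warns(UserWarning):
            assert branching_frequency(topo, 0.0) == 0.0


class TestRowRootCounts:
    def test_three_strips(self):
        m = np.zeros((3, 30), bool)
        m[0, 2:5] = True
        m[1, 2:5] = m[1, 10:15] = True
        m[2, 2:5] = m[2, 10:15] = m[2, 20:24] = True
        med, mx = row_root_counts(mask_from_array(m))
        assert (med, mx) == (2.0, 3)

    def test_single_column_counts_one(self):
        m = np.zeros((10, 5), bool)
        m[:, 0] = True  # root starts at column 0: still one transition
        med, mx = row_root_counts(mask_from_array(m))
        assert (med, mx) == (1.0, 1)

    def test_empty(self):
        assert row_root_counts(mask_from_array(np.zeros((4, 4)))) == (0.0, 0)


class TestExtentMetrics:
    def test_bounding_box(self):
        m = np.zeros((40, 40), bool)
        m[10:20, 5:25] = True
        assert extent_metrics(mask_from_array(m)) == (10.0, 20.0, 2.0)

    def test_single_pixel(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        assert extent_metrics(mask_from_array(m)) == (1.0, 1.0, 1.0)

    def test_vertical_line(self):
        m = np.zeros((60, 10), bool)
        m[5:55, 3] = True
        d, w, r = extent_metrics(mask_from_array(m))
        assert (d, w) == (50.0, 1.0)
        assert r == pytest.approx(0.02)


class TestConvexMetrics:
    def test_solid_rectangle_solidity_one(self):
        m = np.zeros((20, 20), bool)
        m[5:15, 3:18] = True
        mask = mask_from_array(m)
        area = network_area(mask)
        convex_area, solidity = convex_metrics(mask, area)
        assert solidity == pytest.approx(1.0)
        assert convex_area == pytest.approx(area)

    def test_l_shape_strictly_less_than_one(self):
        m = np.zeros((20, 20), bool)
        m[2:18, 2:5] = True
        m[15:18, 2:18] = True
        mask = mask_from_array(m)
        _, solidity = convex_metrics(mask, network_area(mask))
        assert 0 < solidity < 1

    def test_collinear_degenerate_warns(self):
        m = np.zeros((10, 10), bool)
        m[3, 2:8] = True
        mask = mask_from_array(m)
        with pytest.warns(UserWarning):
            convex_area, solidity = convex_metrics(mask, network_area(mask))
        assert solidity == 1.0

    def test_two_corner_dots_hull_is_digital_segment(self):
        m = np.zeros((10, 10), bool)
        m[0, 0] = m[9, 9] = True
        mask = mask_from_array(m)
        convex_area, solidity = convex_metrics(mask, 2.0)
        # oracle: rasterized hull of two points is the digital line segment
        from skimage.draw import line
        rr, cc = line(0, 0, 9, 9)
        assert convex_area == pytest.approx(len(rr))
        assert solidity == pytest.approx(2.0 / len(rr))


class TestLowerRootArea:
    def test_counts_pixels_below_max_radius_pixel(self):
        m = np.zeros((30, 30), bool)
        m[5:25, 10:15] = True
        skel = make_skel([(8, 12), (9, 12), (10, 12)], [1.0, 4.0, 1.0])
        # max radius at row 9: root pixels strictly below are rows 10..24
        assert lower_root_area(mask_from_array(m), skel) == 15 * 5

    def test_max_on_last_row_gives_zero(self):
        m = np.zeros((10, 10), bool)
        m[2:6, 2:4] = True
        skel = make_skel([(5, 2)], 3.0)
        assert lower_root_area(mask_from_array(m), skel) == 0.0

    def test_tie_breaks_topmost(self):
        m = np.zeros((10, 10), bool)
        m[2:8, 4] = True
        skel = make_skel([(r, 4) for r in range(2, 8)], 1.0)
        # all radii equal: the topmost pixel (row 2) wins, area = rows 3..7
        assert lower_root_area(mask_from_array(m), skel) == 5.0


class TestHoleMetrics:
    def test_donut(self):
        m = np.ones((12, 12), bool)
        m[0] = m[-1] = False
        m[:, 0] = m[:, -1] = False
        m[5:8, 5:8] = False
        count, avg = hole_metrics(mask_from_array(m))
        assert (count, avg) == (1, 9.0)

    def test_two_cavities_averaged(self):
        m = np.ones((12, 20), bool)
        m[5, 3:6] = False          # 3 px
        m[5:10, 12] = False        # 5 px
        count, avg = hole_metrics(mask_from_array(m))
        assert (count, avg) == (2, 4.0)

    def test_open_c_shape_has_no_holes(self):
        m = np.zeros((10, 10), bool)
        m[2:8, 2:4] = True
        m[2:4, 2:8] = True
        m[6:8, 2:8] = True
        assert hole_metrics(mask_from_array(m)) == (0, 0.0)


class TestAngleFeatures:
    def test_vertical_line_is_steep(self):
        skel = make_skel([(r, 30) for r in range(5, 60)], shape=(64, 64))
        steep, medium, shallow, avg = angle_features(skel)
        assert steep == 1.0 and medium == 0.0 and shallow == 0.0
        assert avg == pytest.approx(0.0, abs=1.0)

    def test_horizontal_line_is_shallow(self):
        skel = make_skel(hpath(55, r0=30, c0=5), shape=(64, 64))
        steep, medium, shallow, avg = angle_features(skel)
        assert shallow == 1.0
        assert avg == pytest.approx(90.0, abs=1.0)

    def test_diagonal_line_is_medium(self):
        skel = make_skel([(5 + i, 5 + i) for i in range(50)], shape=(64, 64))
        steep, medium, shallow, avg = angle_features(skel)
        assert medium == 1.0
        assert avg == pytest.approx(45.0, abs=1.0)

    def test_frequencies_sum_to_one(self, rng):
        m = random_blob_mask(rng, (40, 40))
        skel = build_skeleton(mask_from_array(m))
        if skel.pixels:
            steep, medium, shallow, _ = angle_features(skel)
            assert steep + medium + shallow == pytest.approx(1.0)


def wire_image(px_per_mm=None):
    """Two clean horizontal bars on a bright background."""
    arr = np.full((60, 120), 230, np.uint8)
    arr[10:15, 10:110] = 40   # 5-px wire
    arr[35:44, 10:110] = 40   # 9-px wire
    return GreyImage(arr, px_per_mm=px_per_mm)


class TestExtractFeatures:
    CFG = dict(threshold_level=191, pruning_enabled=True, pruning_threshold_px=5)

    def test_broken_mode_counts_wire_tips(self):
        rec = extract_features(wire_image(), AnalysisConfig(**self.CFG))
        assert rec.tip_count == 4
        assert rec.branch_point_count == 0
        assert rec.median_roots is None  # whole-root trait absent
        assert rec.network_area == pytest.approx(5 * 100 + 9 * 100)
        assert rec.computation_time_s > 0

    def test_whole_mode_populates_architecture_traits(self):
        cfg = AnalysisConfig(mode="whole_root", **self.CFG)
        rec = extract_features(wire_image(), cfg)
        assert rec.convex_area is not None and rec.convex_area > 0
        assert rec.depth == pytest.approx(34.0)
        # two stacked horizontal wires: every crossed row meets exactly one
        assert rec.max_roots == 1 and rec.median_roots == 1.0
        assert rec.branch_point_count is None

    def test_modes_agree_on_shared_traits(self):
        broken = extract_features(wire_image(), AnalysisConfig(**self.CFG))
        whole = extract_features(wire_image(),
                                 AnalysisConfig(mode="whole_root", **self.CFG))
        for field in ("tip_count", "total_length", "network_area",
                      "avg_diameter", "median_diameter", "max_diameter",
                      "perimeter", "surface_area", "volume"):
            assert getattr(broken, field) == pytest.approx(getattr(whole, field))

    def test_roi_restricts_analysis(self):
        roi = RegionOfInterest("top", 0, 0, 120, 25)  # only the 5-px wire
        rec = extract_features(wire_image(), AnalysisConfig(**self.CFG), roi)
        assert rec.tip_count == 2
        assert rec.network_area == pytest.approx(500)
        assert rec.roi_name == "top"

    def test_unit_conversion(self):
        rec_px = extract_features(wire_image(), AnalysisConfig(**self.CFG))
        rec_mm = extract_features(wire_image(px_per_mm=10.0),
                                  AnalysisConfig(**self.CFG, px_per_mm=10.0))
        assert rec_mm.total_length == pytest.approx(rec_px.total_length / 10)
        assert rec_mm.network_area == pytest.approx(rec_px.network_area / 100)
        assert rec_mm.volume == pytest.approx(rec_px.volume / 1000)

    def test_empty_segmentation_warns_and_zeros(self):
        arr = np.full((20, 20), 250, np.uint8)
        with pytest.warns(UserWarning):
            rec = extract_features(GreyImage(arr), AnalysisConfig(**self.CFG))
        assert rec.tip_count == 0 and rec.total_length == 0.0

    def test_bin_columns_in_row_output(self):
        cfg = AnalysisConfig(diameter_bin_edges=(6.0,), **self.CFG)
        rec = extract_features(wire_image(), cfg)
        row = rec.to_row()
        assert "Root.Length.Range.1" in row and "Root.Length.Range.2" in row
        assert row["Root.Length.Range.1"] + row["Root.Length.Range.2"] == \
            pytest.approx(rec.total_length)
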