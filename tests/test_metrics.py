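import math

import numpy as np
import pytest
from scipy import ndimage

from octaquant import (AnalysisConfig, compute_metric_set, decompose_segments,
                       fractal_dimension, vascular_complexity_index,
                       vascular_tortuosity_index, vessel_density,
                       vessel_diameter_index, vessel_length_density)
from octaquant.metrics import SegmentPath, box_counts
from octaquant.preprocess import VesselMaps, perimeter_of, skeletonize_map
from octaquant.synthetic import make_network, make_shape


class TestDensities:
    def test_vd_extremes_and_count(self):
        assert vessel_density(np.ones((10, 10), bool)) == 100.0
        half = np.zeros((10, 10), bool)
        half[:5] = True
        assert vessel_density(half) == 50.0
        m = np.zeros((100, 100), bool)
        m.ravel()[:1234] = True
        assert vessel_density(m) == pytest.approx(12.34)

    def test_vld_line_and_equality(self):
        assert vessel_length_density(np.zeros((10, 10), bool)) == 0.0
        line = np.zeros((100, 100), bool)
        line[50] = True
        assert vessel_length_density(line) == pytest.approx(1.0)
        # all-1px vessels: VLD == VD
        assert vessel_length_density(line) == vessel_density(line)

    def test_vdi_bar_and_identity(self):
        m = np.zeros((40, 120), bool)
        m[18:23, 10:110] = True
        vd = vessel_density(m)
        vld = vessel_length_density(skeletonize_map(m))
        assert vessel_diameter_index(vd, vld) == pytest.approx(5.0, abs=0.6)
        assert vessel_diameter_index(3.0, 3.0) == 1.0
        assert math.isnan(vessel_diameter_index(3.0, 0.0))

    def test_vdi_increases_with_dilation(self):
        img, truth = make_network(noise_sd=0.0, seed=2, dropout_fraction=0.0)
        sk = skeletonize_map(truth.vessel_mask)
        vld = vessel_length_density(sk)
        previous = -np.inf
        for radius in (1, 2, 3):
            fat = ndimage.binary_dilation(
                truth.vessel_mask, ndimage.generate_binary_structure(2, 1),
                iterations=radius)
            vdi = vessel_diameter_index(vessel_density(fat), vld)
            assert vdi > previous
            previous = vdi

    def test_vdi_inverted_flag(self):
        assert vessel_diameter_index(10.0, 5.0, inverted=True) == pytest.approx(0.5)


class TestFractalDimension:
    def test_line_dimension_one(self):
        m = np.zeros((304, 304), bool)
        m[150] = True
        assert fractal_dimension(m) == pytest.approx(1.0, abs=0.05)

    def test_filled_grid_dimension_two(self):
        assert fractal_dimension(np.ones((304, 304), bool)) == pytest.approx(2.0, abs=0.05)

    def test_single_pixel_dimension_zero(self):
        m = np.zeros((304, 304), bool)
        m[7, 9] = True
        assert fractal_dimension(m) == pytest.approx(0.0, abs=1e-9)

    def test_empty_is_missing(self):
        assert math.isnan(fractal_dimension(np.zeros((32, 32), bool)))

    def test_box_counts_monotone_on_nested_skeletons(self):
        rng = np.random.default_rng(1)
        s2 = rng.random((128, 128)) < 0.05
        s1 = s2 & (rng.random((128, 128)) < 0.5)
        sizes = (2, 4, 8, 16, 32)
        assert (box_counts(s1, sizes) <= box_counts(s2, sizes)).all()

    def test_line_counts_match_enumeration(self):
        # independent oracle: a full-width line occupies ceil(W/s) boxes
        m = np.zeros((304, 304), bool)
        m[150] = True
        sizes = (2, 4, 8, 16, 32)
        expected = [int(np.ceil(304 / s)) for s in sizes]
        assert list(box_counts(m, sizes)) == expected


class TestSegments:
    def test_open_curve_single_segment(self):
        img, truth = make_shape("arc", {"radius": 40, "theta0": 0.3,
                                        "theta1": 2.5}, image_size=121)
        sk = skeletonize_map(truth.vessel_mask)
        segs = decompose_segments(sk)
        long_segs = [s for s in segs if len(s.pixels) > 3]
        assert len(long_segs) == 1

    def test_plus_sign_four_segments(self):
        m = np.zeros((21, 21), bool)
        m[10, :] = True
        m[:, 10] = True
        segs = decompose_segments(m)
        assert len(segs) == 4
        for s in segs:
            assert len(s.pixels) == 11

    def test_loop_split_into_two(self):
        img, truth = make_shape("annulus", {"r_inner": 28, "r_outer": 32},
                                image_size=101)
        sk = skeletonize_map(truth.vessel_mask)
        segs = decompose_segments(sk)
        assert len(segs) == 2
        total = sum(len(s.pixels) - 1 for s in segs)
        assert total >= sk.sum()  # halves share their junction pixels

    def test_every_pixel_covered(self):
        img, truth = make_network(noise_sd=0.0, seed=8, image_size=152)
        sk = skeletonize_map(truth.vessel_mask)
        segs = decompose_segments(sk)
        covered = set()
        for s in segs:
            covered.update(map(tuple, s.pixels))
        frac = len(covered & set(map(tuple, np.argwhere(sk)))) / sk.sum()
        assert frac > 0.99

    def test_segment_invariants(self):
        seg = SegmentPath(np.array([[0, 0], [1, 1], [1, 2], [2, 3]]))
        assert seg.arc_length_px >= seg.chord_length_px > 0
        assert seg.polygon_length_px(3) >= seg.chord_length_px


class TestVTI:
    def test_straight_segments_exactly_one(self):
        horiz = SegmentPath(np.array([[5, c] for c in range(40)]))
        diag = SegmentPath(np.array([[i, i] for i in range(40)]))
        assert vascular_tortuosity_index([horiz, diag]) == pytest.approx(1.0, abs=1e-12)

    def test_semicircle_pi_over_two(self):
        img, truth = make_shape("arc", {"radius": 60, "theta0": 0.0,
                                        "theta1": math.pi}, image_size=141)
        sk = skeletonize_map(truth.vessel_mask)
        segs = decompose_segments(sk)
        vti = vascular_tortuosity_index(segs)
        assert vti == pytest.approx(math.pi / 2, rel=0.05)

    def test_mixture_between_extremes(self):
        straight = SegmentPath(np.array([[0, c] for c in range(30)]))
        wiggly = SegmentPath(np.array(
            [[int(3 * math.sin(c / 2.0) + 5), c] for c in range(30)]))
        lo = vascular_tortuosity_index([straight])
        hi = vascular_tortuosity_index([wiggly])
        mid = vascular_tortuosity_index([straight, wiggly])
        assert lo < mid < hi

    def test_translation_and_rot90_exact(self):
        img, truth = make_network(noise_sd=0.0, seed=5, image_size=152)
        sk = skeletonize_map(truth.vessel_mask)
        vti = vascular_tortuosity_index(decompose_segments(sk))
        padded = np.pad(sk, ((7, 0), (0, 3)))[:sk.shape[0], :sk.shape[1]]
        if padded.sum() == sk.sum():  # translation kept every pixel
            vti_t = vascular_tortuosity_index(decompose_segments(padded))
            assert vti_t == pytest.approx(vti, abs=1e-9)
        vti_r = vascular_tortuosity_index(decompose_segments(np.rot90(sk)))
        assert vti_r == pytest.approx(vti, abs=1e-9)

    def test_rotation_45_within_tolerance(self):
        px = np.zeros((141, 141))
        cols = np.arange(10, 130)
        rows = (70 + 12 * np.sin(2 * np.pi * cols / 60.0)).round().astype(int)
        for off in (-1, 0, 1):  # 3-px band survives nearest-neighbor rotation
            px[rows + off, cols] = 1.0
        sk = skeletonize_map(px > 0)
        vti = vascular_tortuosity_index(decompose_segments(sk))
        rot = ndimage.rotate(px, 45.0, reshape=True, order=0) > 0.5
        sk45 = skeletonize_map(rot)
        vti45 = vascular_tortuosity_index(decompose_segments(sk45))
        assert vti45 == pytest.approx(vti, rel=0.05)

    def test_chain_estimator_available(self):
        cfg = AnalysisConfig(vti_arc_estimator="chain")
        seg = SegmentPath(np.array([[0, 0], [1, 1], [2, 2]]))
        assert vascular_tortuosity_index([seg], cfg) == 1.0

    def test_no_valid_segments_missing(self):
        assert math.isnan(vascular_tortuosity_index([]))


class TestVCI:
    def test_disk_isoperimetric_unity(self):
        img, truth = make_shape("disk", {"radius": 50}, image_size=121)
        vci = vascular_complexity_index(truth.vessel_mask,
                                        perimeter_of(truth.vessel_mask))
        assert vci == pytest.approx(1.0, abs=0.10)

    def test_square_four_over_pi(self):
        img, truth = make_shape("square", {"side": 80}, image_size=121)
        vci = vascular_complexity_index(truth.vessel_mask,
                                        perimeter_of(truth.vessel_mask))
        assert vci == pytest.approx(4 / math.pi, abs=0.10)

    def test_scale_invariance(self):
        small, _ = make_shape("disk", {"radius": 25}, image_size=121)
        big, _ = make_shape("disk", {"radius": 50}, image_size=121)
        v1 = vascular_complexity_index(small.pixels > 0, perimeter_of(small.pixels > 0))
        v2 = vascular_complexity_index(big.pixels > 0, perimeter_of(big.pixels > 0))
        assert v2 == pytest.approx(v1, rel=0.05)

    def test_translation_and_rot90_exact(self):
        img, truth = make_shape("square", {"side": 40, "center_row": 40,
                                           "center_col": 50}, image_size=121)
        m = truth.vessel_mask
        v = vascular_complexity_index(m, perimeter_of(m))
        r = np.rot90(m)
        assert vascular_complexity_index(r, perimeter_of(r)) == pytest.approx(v, abs=1e-12)

    def test_pooled_mode_literal_counts(self):
        img, truth = make_shape("square", {"side": 50}, image_size=121)
        m = truth.vessel_mask
        p = perimeter_of(m)
        cfg = AnalysisConfig(vci_mode="pooled", vci_pixel_counts=True)
        expected = p.sum() ** 2 / (4 * math.pi * m.sum())
        assert vascular_complexity_index(m, p, cfg) == pytest.approx(expected)

    def test_empty_missing(self):
        z = np.zeros((16, 16), bool)
        assert math.isnan(vascular_complexity_index(z, z))


class TestComputeMetricSet:
    def _maps_all_vessel(self, n=64):
        m = np.ones((n, n), bool)
        return VesselMaps(m, m, perimeter_of(m), 0.5, 3000 / 304)

    def test_all_vessel_image(self, config, center_faz):
        maps = self._maps_all_vessel()
        ms = compute_metric_set(maps, center_faz((64, 64)), config)
        assert ms.vd == 100.0
        assert ms.cnp_pct == 0.0
        assert ms.gpd_pct == 0.0

    def test_deterministic(self, config):
        img, truth = make_network(seed=12)
        from octaquant import make_vessel_maps
        maps = make_vessel_maps(img, truth.faz_mask, config)
        a = compute_metric_set(maps, truth.faz_mask, config)
        b = compute_metric_set(maps, truth.faz_mask, config)
        assert a.as_dict() == b.as_dict()

    def test_vd_close_to_truth_on_network(self, config):
        img, truth = make_network(seed=21)  # default speckle noise
        from octaquant import make_vessel_maps
        maps = make_vessel_maps(img, truth.faz_mask, config)
        ms = compute_metric_set(maps, truth.faz_mask, config)
        assert ms.vd == pytest.approx(100 * truth.vessel_mask.mean(), abs=3.0)
        assert ms.vld <= ms.vd
        assert ms.vti >= 1.0
        assert ms.faz_area_mm2 == pytest.approx(
            truth.faz_mask.sum() * (img.pixel_size_um / 1000) ** 2)
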