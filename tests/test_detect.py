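"""Tests for preprocessing and the gradient Hough circle detector."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tillercount import (
    CircleDetection,
    HoughParams,
    count_detections,
    denoise,
    generate_bundle,
    gradient_field,
    hough_circles,
    match_detections,
    to_grayscale,
)
from tillercount.detect import read_detections, write_detections
from tillercount.errors import FormatError, ParameterError
from tillercount.synthetic import _render_annulus

from conftest import small_spec


def annulus_image(shape, circles, background=10.0, wall=2.0):
    img = np.full(shape, background)
    for cx, cy, r in circles:
        _render_annulus(img, cx, cy, r, wall)
    return img


class TestToGrayscale:
    def test_black_and_white(self):
        assert (to_grayscale(np.zeros((4, 4, 3), dtype=np.uint8)) == 0).all()
        assert np.allclose(to_grayscale(np.full((4, 4, 3), 255, dtype=np.uint8)), 255)

    def test_luma_weights(self):
        px = np.array([[[100, 200, 50]]], dtype=np.uint8)
        assert round(float(to_grayscale(px)[0, 0])) == 153

    def test_single_channel_passthrough(self):
        img = np.arange(12, dtype=np.uint8).reshape(3, 4)
        assert (to_grayscale(img) == img).all()

    def test_bad_channel_count(self):
        with pytest.raises(FormatError):
            to_grayscale(np.zeros((4, 4, 2)))


class TestDenoise:
    def test_constant_image_unchanged(self):
        img = np.full((10, 10), 7.0)
        assert (denoise(img) == img).all()

    def test_salt_pixel_removed(self):
        img = np.full((11, 11), 50.0)
        img[5, 5] = 255.0
        assert (denoise(img) == 50.0).all()

    def test_matches_brute_force_windowed_median(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, size=(16, 18)).astype(float)
        k = 5
        pad = k // 2
        padded = np.pad(img, pad, mode="edge")
        expected = np.empty_like(img)
        for i in range(img.shape[0]):
            for j in range(img.shape[1]):
                expected[i, j] = np.median(padded[i : i + k, j : j + k])
        assert (denoise(img, kernel=k) == expected).all()

    def test_even_kernel_rejected(self):
        with pytest.raises(ParameterError):
            denoise(np.zeros((5, 5)), kernel=4)

    def test_gaussian_option_smooths(self):
        img = np.zeros((11, 11))
        img[5, 5] = 100.0
        out = denoise(img, method="gaussian")
        assert 0 < out[5, 5] < 100 and out[5, 4] > 0


class TestGradientField:
    def test_constant_zero_magnitude(self):
        _, _, mag = gradient_field(np.full((8, 8), 3.0))
        assert (mag == 0).all()

    def test_vertical_step_edge(self):
        img = np.zeros((9, 9))
        img[:, 5:] = 255.0
        gx, gy, _ = gradient_field(img)
        assert (gy == 0).all()
        assert (gx[:, 4] > 0).all() and (gx[:, 5] > 0).all()

    def test_ramp_slope_times_stencil_weight(self):
        x = np.arange(10, dtype=float)
        img = np.tile(4 * x, (10, 1))
        gx, gy, _ = gradient_field(img)
        assert (gx[1:-1, 1:-1] == 32.0).all()
        assert (gy[1:-1, 1:-1] == 0.0).all()

    def test_too_small_image(self):
        with pytest.raises(ParameterError):
            gradient_field(np.zeros((2, 5)))


class TestHoughParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"r_min": 30, "r_max": 20},
            {"r_min": 0},
            {"d_min": 0},
            {"p1": -1},
            {"p2": 0},
            {"dp": 0.5},
        ],
    )
    def test_invalid_params(self, kwargs):
        with pytest.raises(ParameterError):
            HoughParams(**kwargs)


class TestHoughCircles:
    def test_blank_image_no_detections(self):
        assert hough_circles(np.full((200, 200), 10.0)) == []

    def test_single_annulus_localized(self):
        img = annulus_image((200, 200), [(100, 100, 30)])
        dets = hough_circles(img)
        assert len(dets) == 1
        d = dets[0]
        assert abs(d.cx - 100) <= 2 and abs(d.cy - 100) <= 2
        assert abs(d.r - 30) <= 2
        assert d.score > 0

    def test_subpixel_center_recovered(self):
        img = annulus_image((200, 200), [(100.5, 87.3, 30)])
        (d,) = hough_circles(img)
        assert abs(d.cx - 100.5) < 1 and abs(d.cy - 87.3) < 1

    def test_grid_of_nine(self):
        centers = [(80 + 120 * j, 80 + 120 * i, 25) for i in range(3) for j in range(3)]
        img = annulus_image((400, 400), centers)
        dets = hough_circles(img)
        assert len(dets) == 9
        m = match_detections(dets, [(c[0], c[1]) for c in centers], 5.0)
        assert m.true_positives == 9

    def test_r_max_too_large_for_image(self):
        with pytest.raises(ParameterError):
            hough_circles(np.zeros((40, 400)), HoughParams(r_max=54))

    def test_determinism(self, small_bundle):
        _, img, _ = small_bundle
        g = denoise(img)
        assert hough_circles(g) == hough_circles(g)

    def test_dmin_separation_and_radius_bounds(self, small_bundle):
        _, img, _ = small_bundle
        params = HoughParams()
        dets = hough_circles(denoise(img), params)
        assert dets, "expected detections on a populated bundle"
        c = np.asarray([(d.cx, d.cy) for d in dets])
        dist = np.hypot(c[:, None, 0] - c[None, :, 0], c[:, None, 1] - c[None, :, 1])
        np.fill_diagonal(dist, np.inf)
        assert (dist >= params.d_min).all()
        assert all(params.r_min <= d.r <= params.r_max for d in dets)

    def test_raising_p2_never_adds_detections(self, small_bundle):
        _, img, _ = small_bundle
        g = denoise(img)
        counts = [
            len(hough_circles(g, HoughParams(p2=p2))) for p2 in (10, 20, 30, 60, 120, 240)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_downscaled_accumulator_keeps_invariants(self):
        img = annulus_image((300, 300), [(90, 90, 30), (210, 200, 35)])
        params = HoughParams(dp=2.0)
        dets = hough_circles(img, params)
        assert dets
        assert all(params.r_min <= d.r <= params.r_max for d in dets)

    def test_recovery_on_clean_bundle(self):
        """Noise- and occluder-free packing: >= 95% of circles recovered."""
        spec = small_spec(
            seed=13, n_tillers=30, radius_range=(26.0, 40.0), min_gap=8.0,
            noise_sd=0.0, mask_shape=(400.0, 360.0),
        )
        img, truth = generate_bundle(spec)
        m = match_detections(hough_circles(denoise(img)), truth, 5.0)
        assert m.recall >= 0.95 and m.precision >= 0.95

    def test_recovery_degrades_monotonically_with_occluders(self):
        recalls = []
        for density in (0.0, 0.05, 0.15):
            spec = small_spec(seed=7, occluder_density=density, noise_sd=0.0)
            img, truth = generate_bundle(spec)
            m = match_detections(hough_circles(denoise(img)), truth, 5.0)
            recalls.append(m.recall)
        assert recalls[0] >= 0.95
        assert recalls[0] >= recalls[1] >= recalls[2]


class TestCountAndIO:
    def test_count_detections(self):
        assert count_detections([]) == 0
        dets = [CircleDetection(1.0, 2.0, 20.0, 1.0)] * 3
        assert count_detections(dets) == 3

    def test_detections_csv_round_trip(self, tmp_path):
        dets = [
            CircleDetection(10.5, 20.25, 22.0, 1.5),
            CircleDetection(100.0, 50.0, 30.0, 0.75),
        ]
        path = tmp_path / "det.csv"
        params = HoughParams()
        write_detections(dets, path, params)
        assert read_detections(path) == dets
        assert path.with_suffix(".params.json").exists()


@settings(max_examples=25, derandomize=True, deadline=None)
@given(
    cx=st.floats(60, 140),
    cy=st.floats(60, 140),
    r=st.floats(21, 40),
)
def test_isolated_annulus_always_found(cx, cy, r):
    """Property: any single in-range annulus is detected within 2 px."""
    img = annulus_image((200, 200), [(cx, cy, r)])
    dets = hough_circles(img)
    assert len(dets) == 1
    d = dets[0]
    assert np.hypot(d.cx - cx, d.cy - cy) <= 2 and abs(d.r - r) <= 2
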