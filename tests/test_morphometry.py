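import numpy as np
import pytest
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse

from mtukit.morphometry import (
    MorphometryScene,
    fusion_index,
    myotube_widths,
    shift_angles,
    texture_variance,
    tube_table,
)
from mtukit.synthetic import gen_morphometry_scene


def toy_scene(labels, marker, nuclei, **kw):
    return MorphometryScene(
        nuclei=np.asarray(nuclei, dtype=float),
        tube_labels=np.asarray(labels),
        marker_positive=marker,
        **kw,
    )


def rect_scene(angle_deg=0.0, width_px=10, length_px=60, shape=(100, 100)):
    """Single rotated-rectangle tube via rotated coordinate masking."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy, cx = shape[0] / 2, shape[1] / 2
    th = np.deg2rad(angle_deg)
    # axis at angle_deg from the y (reference) axis
    along = (xx - cx) * np.sin(th) + (yy - cy) * np.cos(th)
    across = (xx - cx) * np.cos(th) - (yy - cy) * np.sin(th)
    eps = 1e-6  # guard float rounding at the borders for axis-aligned angles
    mask = (np.abs(along) <= length_px / 2 + eps) & (
        np.abs(across) <= width_px / 2 + eps
    )
    return toy_scene(
        mask.astype(int), {1: True}, np.empty((0, 2)), pixel_size_um=2.0
    )


class TestFusionIndex:
    def test_all_nuclei_inside_positive_tubes(self):
        labels = np.zeros((20, 20), int)
        labels[5:15, 5:15] = 1
        scene = toy_scene(labels, {1: True}, [[7, 7], [10, 10], [14, 14]])
        assert fusion_index(scene) == 1.0

    def test_generator_fraction_exact(self):
        scene = gen_morphometry_scene(fusion_fraction=0.25, n_nuclei=40, seed=8)
        assert fusion_index(scene) == 0.25

    def test_marker_negative_tubes_do_not_count(self):
        # three tubes; nuclei in each plus one in background
        labels = np.zeros((30, 30), int)
        labels[2:8, 2:28] = 1
        labels[12:18, 2:28] = 2
        labels[22:28, 2:28] = 3
        marker = {1: True, 2: False, 3: True}
        nuclei = [[5, 5], [5, 15], [5, 25], [29, 29]]
        scene = toy_scene(labels, marker, nuclei)
        assert fusion_index(scene) == pytest.approx(2 / 4)

    def test_boundary_pixel_counts_as_inside(self):
        labels = np.zeros((10, 10), int)
        labels[3:7, 3:7] = 1
        scene = toy_scene(labels, {1: True}, [[3.0, 3.0]])
        assert fusion_index(scene) == 1.0

    def test_zero_nuclei_rejected(self):
        scene = toy_scene(np.zeros((5, 5), int), {}, np.empty((0, 2)))
        with pytest.raises(ValueError, match="no nuclei"):
            fusion_index(scene)

    def test_missing_marker_flag_rejected(self):
        labels = np.zeros((5, 5), int)
        labels[1:3, 1:3] = 2
        with pytest.raises(ValueError, match="missing"):
            toy_scene(labels, {}, [[1, 1]])


class TestShiftAngles:
    def test_parallel_tube_zero_angle(self):
        angles, mean = shift_angles(rect_scene(0.0))
        assert mean == pytest.approx(0.0, abs=0.5)

    def test_perpendicular_tube_ninety_degrees(self):
        angles, mean = shift_angles(rect_scene(90.0))
        assert mean == pytest.approx(90.0, abs=0.5)

    def test_ellipse_at_thirty_degrees(self):
        labels = np.zeros((120, 120), int)
        # major axis at 30 deg from the y axis
        rr, cc = ellipse(60, 60, 40, 8, rotation=np.deg2rad(-30))
        labels[rr, cc] = 1
        scene = toy_scene(labels, {1: True}, np.empty((0, 2)))
        _, mean = shift_angles(scene)
        assert mean == pytest.approx(30.0, abs=1.0)

    def test_round_tube_excluded(self):
        labels = np.zeros((60, 60), int)
        rr, cc = ellipse(30, 30, 10, 10)
        labels[rr, cc] = 1
        angles, mean = shift_angles(toy_scene(labels, {1: True}, np.empty((0, 2))))
        assert len(angles) == 0
        assert np.isnan(mean)

    def test_concentration_ordering_across_seeds(self):
        means = {}
        for kappa in (2.0, 50.0):
            vals = [
                shift_angles(
                    gen_morphometry_scene(
                        angle_concentration=kappa, n_tubes=6, seed=s
                    )
                )[1]
                for s in range(3)
            ]
            means[kappa] = np.mean(vals)
        assert means[50.0] < means[2.0]


class TestMyotubeWidths:
    def test_rectangle_width_in_um(self):
        df = myotube_widths(rect_scene(0.0, width_px=10))
        assert df.loc[1, "width_um"] == pytest.approx(20.0, abs=2.0)
        assert bool(df.loc[1, "reliable"])

    def test_width_invariant_to_rotation(self):
        w0 = myotube_widths(rect_scene(0.0, width_px=10)).loc[1, "width_px"]
        w45 = myotube_widths(rect_scene(45.0, width_px=10)).loc[1, "width_px"]
        assert abs(w0 - w45) <= 1.5

    def test_pixel_size_scales_um_not_px(self):
        scene = rect_scene(0.0, width_px=10)
        scene.pixel_size_um = 4.0
        df = myotube_widths(scene)
        assert df.loc[1, "width_um"] == pytest.approx(
            4.0 * df.loc[1, "width_px"], rel=1e-9
        )

    def test_thin_tube_flagged_unreliable(self):
        labels = np.zeros((30, 30), int)
        labels[5:25, 10] = 1  # 1 px wide
        df = myotube_widths(toy_scene(labels, {1: True}, np.empty((0, 2))))
        assert not bool(df.loc[1, "reliable"])


class TestTextureVariance:
    def test_constant_image_zero(self):
        mask = np.ones((20, 20), bool)
        assert texture_variance(np.full((20, 20), 0.7), mask) == 0.0

    def test_two_valued_closed_form(self):
        img = np.zeros((10, 10))
        img[:5] = 1.0
        assert texture_variance(img, np.ones((10, 10), bool)) == pytest.approx(0.25)

    def test_polygon_roi(self):
        img = np.zeros((20, 20))
        img[:, 10:] = 1.0
        poly = [(0, 0), (9, 0), (9, 19), (0, 19)]  # left half: constant
        assert texture_variance(img, np.asarray(poly, float)) == pytest.approx(0.0)

    def test_fine_texture_has_higher_variance_than_coarse(self, rng):
        # muscle-like fine texture vs tendon-like smooth texture: intensity
        # variance separates the two regions
        raw = rng.standard_normal((80, 160))
        img = np.empty_like(raw)
        img[:, :80] = gaussian_filter(raw[:, :80], 1.5)
        img[:, 80:] = gaussian_filter(raw[:, 80:], 6.0)
        left = np.zeros_like(img, bool)
        left[:, :80] = True
        assert texture_variance(img, left) > texture_variance(img, ~left)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            texture_variance(np.ones((10, 10)), np.zeros((10, 10), bool))


class TestInvariances:
    def test_statistics_invariant_to_translation(self):
        scene = gen_morphometry_scene(seed=4, n_tubes=5, n_nuclei=30)
        h, w = scene.tube_labels.shape
        labels = np.zeros((h + 20, w + 20), dtype=scene.tube_labels.dtype)
        labels[11 : 11 + h, 7 : 7 + w] = scene.tube_labels
        shifted = MorphometryScene(
            nuclei=scene.nuclei + [7, 11],
            tube_labels=labels,
            marker_positive=scene.marker_positive,
            reference_axis=scene.reference_axis,
            pixel_size_um=scene.pixel_size_um,
        )
        assert fusion_index(shifted) == fusion_index(scene)
        a0, m0 = shift_angles(scene)
        a1, m1 = shift_angles(shifted)
        assert m1 == pytest.approx(m0, abs=0.05)

    def test_tube_table_combines_statistics(self):
        scene = gen_morphometry_scene(seed=4, n_tubes=5, n_nuclei=30)
        df = tube_table(scene)
        assert set(df.columns) >= {"width_um", "shift_angle_deg", "marker_positive"}
        assert len(df) == 5
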