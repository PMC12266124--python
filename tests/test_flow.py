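import numpy as np
import pytest

from mtukit.flow import (
    FlowField,
    directional_alignment,
    estimate_flow,
    kinetic_energy,
    segment_voids,
    subtraction_displacement,
    visualize_flow,
)
from mtukit.synthetic import (
    SyntheticVideoSpec,
    Translation,
    UniaxialContraction,
    gen_video,
)


def video(model, **kw):
    spec = SyntheticVideoSpec(motion_model=model, seed=11, **kw)
    return gen_video(spec)


class TestEstimateFlow:
    def test_identical_frames_give_zero_field(self, rng):
        frame = rng.random((64, 64))
        fl = estimate_flow(frame, frame)
        assert np.abs(fl.magnitude).max() < 1e-3

    def test_translation_recovered_within_contract(self):
        frames, _ = video(Translation(2.0, 0.0))
        fl = estimate_flow(frames[0], frames[1])
        epe = np.hypot(fl.u - 2.0, fl.v).mean()
        assert epe < 0.2
        assert fl.u.mean() == pytest.approx(2.0, abs=0.2)

    def test_contraction_divergence_negative_over_tissue(self):
        frames, _ = video(UniaxialContraction(0.01, axis="x"))
        fl = estimate_flow(frames[0], frames[1])
        du_dx = np.gradient(fl.u, axis=1)
        interior = np.zeros_like(du_dx, dtype=bool)
        interior[8:-8, 8:-8] = True
        assert (du_dx[interior] < 0).mean() >= 0.95

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError, match="shapes differ"):
            estimate_flow(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_error_degrades_gracefully_with_noise(self):
        epes = []
        for noise in (0.0, 0.04, 0.12):
            frames, _ = video(Translation(2.0, 0.0), noise_sd=noise)
            fl = estimate_flow(frames[0], frames[1])
            epes.append(float(np.hypot(fl.u - 2.0, fl.v).mean()))
        assert epes[0] <= epes[1] * 1.05
        assert epes[1] <= epes[2] * 1.05

    def test_tvl1_backend_also_meets_contract(self):
        frames, _ = video(Translation(1.0, 1.0))
        fl = estimate_flow(frames[0], frames[1], backend="tvl1")
        assert np.hypot(fl.u - 1.0, fl.v - 1.0).mean() < 0.2


class TestDirectionalAlignment:
    def test_field_exactly_at_angle(self):
        n = 32
        f = FlowField(
            np.full((n, n), -np.sqrt(0.5)), np.full((n, n), -np.sqrt(0.5))
        )  # up-left in display orientation = 135 degrees
        count, frac = directional_alignment(f, 135.0, 22.5)
        assert frac == 1.0
        assert count == n * n

    def test_orthogonal_field_excluded(self):
        f = FlowField(np.ones((16, 16)), np.zeros((16, 16)))
        _, frac = directional_alignment(f, 135.0, 22.5)
        assert frac == 0.0

    def test_magnitude_floor_excludes_noise_vectors(self):
        u = np.full((10, 10), 0.01)
        f = FlowField(u, u)
        count, frac = directional_alignment(f, 45.0, 22.5, magnitude_floor=0.1)
        assert (count, frac) == (0, 0.0)

    def test_isotropic_field_matches_angular_measure(self, rng):
        th = rng.uniform(0, 2 * np.pi, 10**6)
        f = FlowField(np.cos(th), -np.sin(th))
        _, frac = directional_alignment(f, 135.0, 22.5)
        se = np.sqrt(0.125 * 0.875 / 1e6)
        assert abs(frac - 0.125) < 3 * se

    def test_disjoint_bins_tile_the_circle(self, rng):
        th = rng.uniform(0, 2 * np.pi, 20000)
        f = FlowField(np.cos(th), np.sin(th))
        total = sum(
            directional_alignment(f, c, 22.4999)[1]
            for c in np.arange(0, 360, 45)
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_invalid_tolerance_rejected(self):
        f = FlowField(np.ones((4, 4)), np.zeros((4, 4)))
        with pytest.raises(ValueError):
            directional_alignment(f, 0.0, 200.0)


class TestKineticEnergy:
    def test_uniform_speed_closed_form(self):
        # 1 mm/s everywhere at rho = 1000 -> Ek = 5e-4 J/m^3
        f = FlowField(
            np.ones((40, 40)),
            np.zeros((40, 40)),
            pixel_size_um=40.0,
            frame_interval_s=0.04,
        )
        trace = kinetic_energy(f, np.ones((40, 40), bool), rho_kg_m3=1000.0)
        assert trace.values[0] == pytest.approx(5e-4, rel=1e-12)

    def test_zero_flow_zero_energy(self):
        f = FlowField(np.zeros((8, 8)), np.zeros((8, 8)))
        assert kinetic_energy(f, np.ones((8, 8), bool)).values[0] == 0.0

    def test_two_region_field_matches_brute_force(self):
        u = np.zeros((10, 10))
        u[:5] = 1.0
        u[5:] = 3.0
        f = FlowField(u, np.zeros_like(u), pixel_size_um=1.0, frame_interval_s=1.0)
        mask = np.ones((10, 10), bool)
        trace = kinetic_energy(f, mask, rho_kg_m3=1000.0)
        # independent per-pixel summation
        v = f.speed_m_per_s()
        expected = 0.5 * 1000.0 * sum(v[i, j] ** 2 for i in range(10) for j in range(10)) / 100
        assert trace.values[0] == pytest.approx(expected, rel=1e-12)

    def test_mask_excludes_void_pixels(self):
        u = np.ones((10, 10))
        u[0, 0] = 100.0
        f = FlowField(u, np.zeros_like(u))
        mask = np.ones((10, 10), bool)
        mask[0, 0] = False
        v = f.speed_m_per_s()
        expected = 0.5 * 1000.0 * float((v[mask] ** 2).mean())
        assert kinetic_energy(f, mask).values[0] == pytest.approx(expected)

    def test_empty_mask_rejected(self):
        f = FlowField(np.ones((4, 4)), np.zeros((4, 4)))
        with pytest.raises(ValueError, match="empty"):
            kinetic_energy(f, np.zeros((4, 4), bool))

    def test_invariant_to_intensity_rescaling(self):
        frames, _ = video(Translation(1.5, 0.0))
        mask = np.ones(frames[0].shape, bool)
        e1 = kinetic_energy(
            estimate_flow(frames[0], frames[1]), mask
        ).values[0]
        e2 = kinetic_energy(
            estimate_flow(0.4 * frames[0], 0.4 * frames[1]), mask
        ).values[0]
        assert e2 == pytest.approx(e1, rel=1e-3)

    def test_quadratic_scaling_with_speed(self):
        speeds = [0.5, 1.0, 2.0]
        eks = []
        for s in speeds:
            frames, _ = video(Translation(s, 0.0))
            fl = estimate_flow(frames[0], frames[1])
            eks.append(kinetic_energy(fl, np.ones(fl.u.shape, bool)).values[0])
        slope = np.polyfit(np.log(speeds), np.log(eks), 1)[0]
        assert slope == pytest.approx(2.0, abs=0.05)


class TestSegmentVoids:
    def test_uniform_bright_frame_empty_mask(self):
        assert not segment_voids(np.full((64, 64), 0.8)).any()

    def test_dark_rectangle_area_recovered(self):
        # rectangle covering ~10% of the frame
        frames, truth = video(
            Translation(0.0, 0.0),
            void_rects=((20, 30, 50, 40),),
            noise_sd=0.005,
            width_px=140,
            height_px=140,
        )
        mask = segment_voids(frames[0])
        true_area = truth.void_mask.sum()
        assert abs(int(mask.sum()) - true_area) / true_area < 0.05

    def test_polarity_inversion_symmetric(self):
        frames, truth = video(
            Translation(0.0, 0.0),
            void_rects=((20, 30, 50, 40),),
            noise_sd=0.005,
            width_px=140,
            height_px=140,
        )
        dark = segment_voids(frames[0])
        bright = segment_voids(1.0 - frames[0], invert=True)
        overlap = (dark & bright).sum() / max(dark.sum(), 1)
        assert overlap > 0.9


class TestSubtractionDisplacement:
    def test_identical_frames(self, rng):
        f = rng.random((48, 48))
        diff, d = subtraction_displacement(f, f)
        assert np.all(diff == 0)
        assert d == 0.0

    def test_known_shift_recovered_in_um(self):
        frames, _ = video(Translation(3.0, 0.0), noise_sd=0.0)
        _, d = subtraction_displacement(
            frames[0], frames[1], axis="x", pixel_size_um=2.0
        )
        assert d == pytest.approx(6.0, abs=2.0)  # within one pixel equivalent

    def test_featureless_frames_undefined(self):
        a = np.full((32, 32), 0.5)
        _, d = subtraction_displacement(a, a + 0.01)
        assert np.isnan(d)

    def test_difference_concentrates_at_edges(self):
        # a shifted dark rectangle: the difference image lives in the band
        # swept by its vertical edges
        a = np.full((60, 60), 0.9)
        a[20:40, 20:40] = 0.1
        b = np.full((60, 60), 0.9)
        b[20:40, 23:43] = 0.1
        diff, _ = subtraction_displacement(a, b)
        edge_band = np.zeros_like(a, dtype=bool)
        edge_band[20:40, 20:23] = True
        edge_band[20:40, 40:43] = True
        detected = diff > 0.5 * diff.max()
        iou = (detected & edge_band).sum() / (detected | edge_band).sum()
        assert iou > 0.5


class TestVisualizeFlow:
    def test_zero_fraction_leaves_background(self, rng):
        bg = rng.random((32, 32))
        f = FlowField(np.ones((32, 32)), np.zeros((32, 32)))
        out = visualize_flow(f, background=bg, sample_fraction=0.0)
        expected = np.repeat(
            (np.clip((bg - bg.min()) / (bg.max() - bg.min()), 0, 1) * 255)
            .astype(np.uint8)[:, :, None],
            3,
            axis=2,
        )
        assert np.array_equal(out, expected)

    def test_uniform_field_single_hue(self):
        f = FlowField(np.ones((100, 100)), np.zeros((100, 100)))
        out = visualize_flow(f, sample_fraction=0.01, seed=0)
        colors = np.unique(out.reshape(-1, 3), axis=0)
        colors = colors[colors.any(axis=1)]  # drop background black
        assert len(colors) == 1

    def test_deterministic_given_seed(self):
        f = FlowField(np.ones((64, 64)), np.ones((64, 64)))
        a = visualize_flow(f, sample_fraction=0.005, seed=4)
        b = visualize_flow(f, sample_fraction=0.005, seed=4)
        assert np.array_equal(a, b)
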