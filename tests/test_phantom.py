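import numpy as np
import pytest

from retnav.core_io import LaserParams, check_surface_order
from retnav.phantom import (
    PhantomParams,
    apply_lesion,
    generate_grid_target,
    generate_retina_volume,
    generate_slo_sequence,
    photoconverted_fraction_map,
    small_params,
)


class TestRetinaVolume:
    def test_noise_free_limit_repeats_identical(self):
        p = small_params(seed=1, speckle_contrast=0.0, noise_floor=0.0, shape=(8, 8, 64))
        vol, _ = generate_retina_volume(p)
        for r in range(1, vol.n_repeats):
            np.testing.assert_array_equal(vol.voxels[r], vol.voxels[0])

    def test_noise_free_profile_matches_layer_model(self):
        p = small_params(seed=1, speckle_contrast=0.0, noise_floor=0.0,
                         curvature_um=0.0, vessels=(), shape=(4, 4, 128))
        vol, _ = generate_retina_volume(p)
        z_um = (np.arange(128) + 0.5) * p.pitch_z
        expected = np.zeros(128)
        for _, depth, thick, refl in p.layers:
            expected += refl * np.exp(-((z_um - depth) ** 2) / (2 * (thick / 2.355) ** 2))
        np.testing.assert_allclose(vol.voxels[0, 0, 0], expected, rtol=1e-5, atol=1e-6)

    def test_repeat_noise_matches_speckle_model(self):
        # per-voxel std across repeats ~ sqrt((c * clean)^2 + floor^2)
        p = small_params(seed=2, shape=(16, 16, 128), n_repeats=40, vessels=(),
                         curvature_um=0.0)
        vol, truth = generate_retina_volume(p)
        clean = generate_retina_volume(
            small_params(seed=2, shape=(16, 16, 128), n_repeats=1, vessels=(),
                         curvature_um=0.0, speckle_contrast=0.0, noise_floor=0.0)
        )[0].voxels[0]
        bright = clean > 0.5  # avoid the clipped-at-zero background
        pred_var = (p.speckle_contrast * clean[bright]) ** 2 + p.noise_floor**2
        obs_var = vol.voxels.var(axis=0, ddof=1)[bright]
        ratio = np.sqrt(obs_var.mean() / pred_var.mean())
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_zero_curvature_flat_rpe(self):
        p = small_params(seed=3, curvature_um=0.0, shape=(8, 8, 64))
        _, truth = generate_retina_volume(p)
        assert np.unique(truth.surfaces["RPE"].depth).size == 1

    def test_vessel_shadows_attenuate_below(self):
        p = small_params(seed=4, speckle_contrast=0.0, noise_floor=0.0,
                         curvature_um=0.0, shape=(32, 32, 128),
                         vessels=(("x", 128.0, 12.0),))
        vol, truth = generate_retina_volume(p)
        rpe = int(truth.surfaces["RPE"].depth[0, 0])
        on_vessel = vol.voxels[0, 16, :, rpe]  # y row under the vessel centreline
        off_vessel = vol.voxels[0, 0, :, rpe]
        assert on_vessel.max() < 0.5 * off_vessel.min()

    def test_surfaces_satisfy_order_invariant(self, small_phantom):
        _, _, truth = small_phantom
        check_surface_order(truth.surfaces["OPL"], truth.surfaces["RPE"])

    def test_determinism(self):
        p = small_params(seed=11, shape=(6, 6, 64))
        v1, _ = generate_retina_volume(p)
        v2, _ = generate_retina_volume(p)
        np.testing.assert_array_equal(v1.voxels, v2.voxels)

    def test_layer_order_validated(self):
        with pytest.raises(ValueError, match="OPL"):
            PhantomParams(layers=(("RPE", 100.0, 20.0, 1.0), ("OPL", 200.0, 20.0, 0.7)))


class TestLesionResponse:
    def _setup(self, **kw):
        p = small_params(seed=5, shape=(32, 32, 128), **kw)
        vol, truth = generate_retina_volume(p)
        return p, vol, truth

    def test_zero_energy_is_identity(self):
        p, vol, truth = self._setup(speckle_contrast=0.0, noise_floor=0.0)
        vol2, truth = apply_lesion(vol, (128.0, 128.0), LaserParams(1e-9, 1e-6), p, truth)
        np.testing.assert_allclose(vol2.voxels, vol.voxels, rtol=1e-6)
        assert truth.lesion_mask.sum() == 0

    def test_pulse_accumulation_monotone(self):
        # 4 pulses at 6 mW / 200 ms produce more gain than 1 pulse at the same site
        p, vol, truth1 = self._setup(speckle_contrast=0.0, noise_floor=0.0)
        one, truth1 = apply_lesion(vol, (128.0, 128.0), LaserParams(6, 200, 1), p, truth1)
        _, _, truth4 = self._setup(speckle_contrast=0.0, noise_floor=0.0)
        four, truth4 = apply_lesion(vol, (128.0, 128.0), LaserParams(6, 200, 4), p, truth4)
        mask = truth1.lesion_mask
        base = generate_retina_volume(p)[0]
        gain1 = (one.voxels[0][mask] / base.voxels[0][mask]).mean()
        gain4 = (four.voxels[0][mask] / base.voxels[0][mask]).mean()
        assert gain4 > gain1
        assert truth4.lesion_mask.sum() >= truth1.lesion_mask.sum()

    def test_repeated_calls_accumulate_energy(self):
        p, vol, truth = self._setup()
        vol, truth = apply_lesion(vol, (128.0, 128.0), LaserParams(6, 200, 1), p, truth)
        vol, truth = apply_lesion(vol, (128.0, 128.0), LaserParams(6, 200, 3), p, truth)
        assert truth.sites == [{"x_um": 128.0, "y_um": 128.0, "energy_mj": pytest.approx(4.8)}]

    def test_axial_extent_matches_closed_form(self):
        # mask axial extent ratio at E = 2*E0 vs E = E0 equals the closed form
        # min(growth * E, RPE - OPL) evaluated directly
        p, vol, truth = self._setup(speckle_contrast=0.0, noise_floor=0.0, curvature_um=0.0)
        extents = {}
        for e_mult in (1.0, 2.0):
            _, _, t = self._setup(speckle_contrast=0.0, noise_floor=0.0, curvature_um=0.0)
            energy = e_mult * p.lesion_e0_mj
            _, t = apply_lesion(vol, (128.0, 128.0),
                                LaserParams(energy * 1000, 1.0, 1), p, t)
            zs = np.nonzero(t.lesion_mask.any(axis=(0, 1)))[0]
            extents[e_mult] = zs.max() - zs.min() + 1
        d_um = p.layer_depth("RPE") - p.layer_depth("OPL")
        expect = lambda e: min(p.axial_growth_um_per_mj * e, d_um) / p.pitch_z
        expected_ratio = expect(2 * p.lesion_e0_mj) / expect(p.lesion_e0_mj)
        assert extents[2.0] / extents[1.0] == pytest.approx(expected_ratio, rel=0.25)

    def test_site_outside_field_rejected(self):
        p, vol, truth = self._setup()
        with pytest.raises(ValueError, match="outside"):
            apply_lesion(vol, (10_000.0, 128.0), LaserParams(6, 200), p, truth)

    def test_mask_volume_monotone_in_energy(self):
        p = small_params(seed=6, shape=(24, 24, 128))
        vol, _ = generate_retina_volume(p)
        sizes = []
        for e in (0.6, 1.2, 4.8, 12.0):
            from retnav.phantom import GroundTruth

            _, truth = generate_retina_volume(p)
            _, truth = apply_lesion(vol, (96.0, 96.0), LaserParams(e * 1000, 1.0), p, truth)
            sizes.append(truth.lesion_mask.sum())
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))
        assert sizes[0] > 0


class TestSLOSequence:
    def test_zero_kappa_no_green_lesion_signal(self):
        p = small_params(seed=7, kappa_per_mj=0.0, slo_frames=6, slo_noise=0.0,
                         motion_rate_hz=0.0, vessels=())
        seq, _ = generate_slo_sequence(p, sites=[{"x_um": 256.0, "y_um": 256.0,
                                                  "energy_mj": 10.0}])
        assert np.all(np.abs(seq.green() - p.green_baseline) < 1e-5)

    def test_full_conversion_limit(self):
        # very high energy -> phi ~ 1: red channel extinguished at the lesion
        p = small_params(seed=8, slo_frames=6, slo_noise=0.0, motion_rate_hz=0.0,
                         vessels=())
        phi = photoconverted_fraction_map(
            p, [{"x_um": 256.0, "y_um": 256.0, "energy_mj": 1e6}], p.slo_shape
        )
        centre = phi[128, 128]
        assert centre == pytest.approx(1.0, abs=1e-6)
        assert phi.min() >= 0.0 and phi.max() <= 1.0

    def test_phi_strictly_increasing_in_energy(self):
        p = small_params(seed=8)
        phis = [
            photoconverted_fraction_map(
                p, [{"x_um": 9.0, "y_um": 9.0, "energy_mj": e}], (8, 8)
            )[4, 4]
            for e in (0.5, 1.0, 2.0, 4.0)
        ]
        assert all(a < b for a, b in zip(phis, phis[1:]))

    def test_corrupted_frame_count_matches_poisson_expectation(self):
        # motion 1.5 Hz over 200 frames at 7.8 Hz: E[corrupted] = 200 * 1.5 / 7.8
        counts = []
        for seed in range(100):
            p = small_params(seed=seed, slo_shape=(16, 16), slo_frames=200,
                             slo_noise=0.0, vessels=())
            _, truth = generate_slo_sequence(p)
            counts.append(len(truth.corrupted_frames))
        lam = 200 * 1.5 / 7.8
        se = np.sqrt(lam / 100)
        assert abs(np.mean(counts) - lam) < 4 * se

    def test_determinism(self):
        p = small_params(seed=9, slo_shape=(32, 32), slo_frames=10)
        s1, t1 = generate_slo_sequence(p, sites=[{"x_um": 10.0, "y_um": 20.0, "energy_mj": 2.0}])
        s2, t2 = generate_slo_sequence(p, sites=[{"x_um": 10.0, "y_um": 20.0, "energy_mj": 2.0}])
        np.testing.assert_array_equal(s1.frames, s2.frames)
        assert t1.corrupted_frames == t2.corrupted_frames


class TestGridTarget:
    def test_zero_distortion_observed_equals_commanded(self):
        g = generate_grid_target(seed=1)
        np.testing.assert_allclose(
            g.landmarks[["x_um", "y_um"]].to_numpy(),
            g.landmarks[["x_true_um", "y_true_um"]].to_numpy(),
            atol=1e-12,
        )

    def test_rotation_90_preserves_landmark_multiset(self):
        g0 = generate_grid_target(seed=1, rotation_deg=0.0)
        g90 = generate_grid_target(seed=1, rotation_deg=90.0)
        a = np.sort(np.round(g0.landmarks[["x_um", "y_um"]].to_numpy(), 6), axis=0)
        b = np.sort(np.round(g90.landmarks[["x_um", "y_um"]].to_numpy(), 6), axis=0)
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_quadratic_distortion_matches_polynomial_evaluation(self):
        from numpy.polynomial import polynomial as npoly

        cx = np.array([[400.0, 3.0, 0.0], [480.0, 2.0, 0.0], [5.0, 0.0, 0.0]])
        cy = np.array([[410.0, 490.0, -4.0], [1.0, 2.5, 0.0], [0.0, 0.0, 0.0]])
        g = generate_grid_target(seed=2, distortion=(cx, cy))
        v = g.landmarks[["vx", "vy"]].to_numpy()
        np.testing.assert_allclose(
            g.landmarks["x_um"], npoly.polyval2d(v[:, 0], v[:, 1], cx), rtol=1e-12
        )
        np.testing.assert_allclose(
            g.landmarks["y_um"], npoly.polyval2d(v[:, 0], v[:, 1], cy), rtol=1e-12
        )

    def test_invalid_spacing_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            generate_grid_target(spacing_um=0.0)
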