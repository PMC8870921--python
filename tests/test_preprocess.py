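import logging

import numpy as np
import pytest

from lesionquant import (BinaryMask, DiffusionConfig, RigidTransform2D, Volume,
                         anisotropic_diffuse, apply_mask, apply_transform,
                         correct_bias, estimate_bias_field, make_phantom,
                         minmax_rescale, register_rigid_inplane,
                         reslice_isotropic, resize_inplane, zscore_normalize)


class TestReslice:
    def test_clinical_grid_to_isotropic(self):
        v = Volume(np.zeros((100, 100, 20)), (0.43, 0.43, 4.6))
        out = reslice_isotropic(v, (1.0, 1.0, 1.0))
        assert out.shape == (43, 43, 92)
        assert out.spacing == (1.0, 1.0, 1.0)

    def test_identity_target(self, random_volume):
        out = reslice_isotropic(random_volume, random_volume.spacing)
        np.testing.assert_allclose(out.data, random_volume.data, atol=1e-10)

    def test_constant_preserved(self):
        v = Volume(np.full((10, 10, 4), 3.7), (2.0, 2.0, 2.0))
        out = reslice_isotropic(v, (1.0, 1.0, 1.0))
        np.testing.assert_allclose(out.data, 3.7, atol=1e-9)

    def test_mask_stays_binary(self, rng):
        m = BinaryMask((rng.random((20, 20, 6)) > 0.5).astype(np.uint8), (2, 2, 3))
        out = reslice_isotropic(m, (1.0, 1.0, 1.0))
        assert isinstance(out, BinaryMask)
        assert set(np.unique(out.data)) <= {0, 1}

    def test_degenerate_target(self, random_volume):
        with pytest.raises(ValueError):
            reslice_isotropic(random_volume, (1.0, -1.0, 1.0))


class TestDiffusion:
    def test_constant_image_is_fixed_point(self):
        v = Volume(np.full((16, 16, 2), 5.0), (1, 1, 1))
        out = anisotropic_diffuse(v, DiffusionConfig(iterations=20))
        np.testing.assert_array_equal(out.data, v.data)

    def test_intensity_sum_conserved(self, rng):
        v = Volume(rng.random((32, 32, 3)) * 100, (1, 1, 1))
        out = anisotropic_diffuse(v, DiffusionConfig(iterations=15, kappa=10))
        for k in range(3):
            before = v.data[:, :, k].sum()
            after = out.data[:, :, k].sum()
            assert abs(after - before) <= 1e-6 * abs(before)

    def test_within_region_variance_decreases(self, rng):
        # noisy piecewise-constant slice: left half 10, right half 50
        sl = np.where(np.arange(32)[None, :] < 16, 10.0, 50.0) + np.zeros((32, 32))
        noisy = sl + rng.normal(0, 1.0, sl.shape)
        v = Volume(noisy[:, :, None], (1, 1, 1))
        out = anisotropic_diffuse(v, DiffusionConfig(iterations=10, kappa=5))
        region = out.data[:, :12, 0]
        assert region.var() < noisy[:, :12].var()

    def test_total_variation_monotone(self, rng):
        sl = rng.random((24, 24)) * 10
        def tv(a):
            return np.abs(np.diff(a, axis=0)).sum() + np.abs(np.diff(a, axis=1)).sum()
        prev = tv(sl)
        v = Volume(sl[:, :, None], (1, 1, 1))
        for _ in range(8):
            v = anisotropic_diffuse(v, DiffusionConfig(iterations=1, kappa=3))
            cur = tv(v.data[:, :, 0])
            assert cur <= prev + 1e-9
            prev = cur

    def test_invalid_dt(self):
        with pytest.raises(ValueError, match="dt"):
            DiffusionConfig(dt=0.3)


class TestRigidTransform:
    def test_inverse_composition_is_identity(self, rng):
        for _ in range(20):
            T = RigidTransform2D(*rng.uniform(-5, 5, 2), rng.uniform(-0.5, 0.5))
            I = T.compose(T.inverse())
            assert abs(I.tx) < 1e-12 and abs(I.ty) < 1e-12 and abs(I.theta) < 1e-12

    def test_theta_wrapped(self):
        T = RigidTransform2D(0, 0, 3 * np.pi)
        assert -np.pi < T.theta <= np.pi

    def test_identity_transform_identity_resample(self, random_volume):
        out = apply_transform(random_volume, RigidTransform2D())
        np.testing.assert_allclose(out.data, random_volume.data, atol=1e-9)

    def test_round_trip_on_smooth_image(self):
        x, y = np.meshgrid(np.linspace(0, 1, 48), np.linspace(0, 1, 48), indexing="ij")
        smooth = np.sin(3 * x) * np.cos(2 * y)
        v = Volume(np.repeat(smooth[:, :, None], 2, axis=2), (1, 1, 1))
        T = RigidTransform2D(2.0, -1.5, 0.1)
        back = apply_transform(apply_transform(v, T), T.inverse())
        core = (slice(8, -8), slice(8, -8), slice(None))
        rng_dyn = v.data.max() - v.data.min()
        assert np.abs(back.data[core] - v.data[core]).max() < 0.01 * rng_dyn

    def test_mask_nearest_stays_binary(self, rng):
        m = BinaryMask((rng.random((16, 16, 2)) > 0.5).astype(np.uint8), (1, 1, 1))
        out = apply_transform(m, RigidTransform2D(1.2, -0.7, 0.05))
        assert set(np.unique(out.data)) <= {0, 1}


class TestRegistration:
    def test_self_registration_is_identity(self):
        case = make_phantom(__import__("lesionquant").PhantomSpec(
            noise_sigma=0.01, max_shift_mm=0, max_rotation_rad=0, seed=3))
        T, _ = register_rigid_inplane(case.t1, case.t1)
        assert abs(T.tx) < 0.1 and abs(T.ty) < 0.1 and abs(T.theta) < 0.005

    def test_known_misalignment_recovered(self):
        from lesionquant import PhantomSpec
        spec = PhantomSpec(noise_sigma=0.01, bias_amplitude=0.0,
                           max_shift_mm=0, max_rotation_rad=0, seed=5)
        case = make_phantom(spec)
        T_inj = RigidTransform2D(3.0, -2.0, 0.05)
        moved = apply_transform(case.flair, T_inj)
        T, _ = register_rigid_inplane(moved, case.t1)
        T_exp = T_inj.inverse()
        assert abs(T.tx - T_exp.tx) < 0.5
        assert abs(T.ty - T_exp.ty) < 0.5
        assert abs(T.theta - T_exp.theta) < 0.01

    def test_noise_vs_noise_converges(self, rng):
        a = Volume(rng.random((32, 32, 4)), (1, 1, 1))
        b = Volume(rng.random((32, 32, 4)), (1, 1, 1))
        T, out = register_rigid_inplane(a, b)
        assert np.isfinite([T.tx, T.ty, T.theta]).all()
        assert np.isfinite(out.data).all()

    def test_shape_mismatch_rejected(self, rng):
        a = Volume(rng.random((16, 16, 2)), (1, 1, 1))
        b = Volume(rng.random((16, 16, 3)), (1, 1, 1))
        with pytest.raises(ValueError, match="shape"):
            register_rigid_inplane(a, b)


class TestNormalisation:
    def test_zscore_closed_form(self):
        sl = np.array([2.0, 4.0, 6.0, 8.0]).reshape(2, 2, 1)
        out = zscore_normalize(Volume(sl, (1, 1, 1)))
        np.testing.assert_allclose(out.data, (sl - 5.0) / np.sqrt(5.0))
        assert abs(out.data.mean()) < 1e-6
        assert abs(out.data.std() - 1) < 1e-6

    def test_zscore_idempotent(self, rng):
        v = zscore_normalize(Volume(rng.random((8, 8, 3)), (1, 1, 1)))
        again = zscore_normalize(v)
        np.testing.assert_allclose(again.data, v.data, atol=1e-6)

    def test_constant_slice_zeroed_with_warning(self, caplog):
        data = np.ones((4, 4, 2))
        data[:, :, 1] = np.arange(16).reshape(4, 4)
        with caplog.at_level(logging.WARNING, logger="lesionquant.preprocess"):
            out = zscore_normalize(Volume(data, (1, 1, 1)))
        assert np.all(out.data[:, :, 0] == 0)
        assert "constant slice" in caplog.text

    def test_minmax_closed_form(self):
        v = Volume(np.array([2.0, 4.0, 6.0]).reshape(1, 3, 1), (1, 1, 1))
        np.testing.assert_allclose(minmax_rescale(v).data.ravel(), [0, 0.5, 1])

    def test_minmax_range(self, rng):
        out = minmax_rescale(Volume(rng.normal(size=(8, 8, 2)), (1, 1, 1)))
        assert out.data.min() == 0.0 and out.data.max() == 1.0

    def test_minmax_constant_zeroed(self, caplog):
        with caplog.at_level(logging.WARNING, logger="lesionquant.preprocess"):
            out = minmax_rescale(Volume(np.full((4, 4, 1), 2.0), (1, 1, 1)))
        assert np.all(out.data == 0)


class TestResize:
    def test_identity_shape(self, random_volume):
        out = resize_inplane(random_volume, random_volume.shape[:2])
        np.testing.assert_allclose(out.data, random_volume.data)

    def test_target_shape_and_extent(self, rng):
        v = Volume(rng.random((40, 20, 3)), (0.5, 1.0, 2.0))
        out = resize_inplane(v, (64, 64))
        assert out.shape == (64, 64, 3)
        # physical in-plane extent preserved
        assert out.spacing[0] * 64 == pytest.approx(0.5 * 40)
        assert out.spacing[1] * 64 == pytest.approx(1.0 * 20)

    def test_mask_stays_binary(self, rng):
        m = BinaryMask((rng.random((20, 20, 2)) > 0.5).astype(np.uint8), (1, 1, 1))
        out = resize_inplane(m, (32, 32))
        assert set(np.unique(out.data)) <= {0, 1}


class TestBiasField:
    def _uniform_brain(self):
        data = np.full((24, 24, 8), 100.0)
        m = np.zeros((24, 24, 8), dtype=np.uint8)
        m[4:20, 4:20, 1:7] = 1
        return Volume(data, (1, 1, 1)), BinaryMask(m, (1, 1, 1))

    def test_bias_free_phantom_gives_flat_field(self):
        v, m = self._uniform_brain()
        field = estimate_bias_field(v, m, order=3)
        inside = field.data[m.data.astype(bool)]
        assert np.abs(inside - 1.0).max() < 0.02

    def test_linear_ramp_recovered(self):
        v, m = self._uniform_brain()
        ramp = np.linspace(0.8, 1.2, 24)[:, None, None] * np.ones_like(v.data)
        biased = Volume(v.data * ramp, v.spacing)
        field = estimate_bias_field(biased, m, order=3)
        inside = m.data.astype(bool)
        r = np.corrcoef(field.data[inside], ramp[inside])[0, 1]
        assert r > 0.95

    def test_mean_one_over_mask(self, rng):
        v, m = self._uniform_brain()
        noisy = Volume(v.data * (1 + 0.3 * rng.random(v.shape)), v.spacing)
        field = estimate_bias_field(noisy, m, order=2)
        assert field.data[m.data.astype(bool)].mean() == pytest.approx(1.0, abs=1e-6)
        assert field.data.min() > 0

    def test_empty_mask_rejected(self):
        v, _ = self._uniform_brain()
        with pytest.raises(ValueError, match="empty"):
            estimate_bias_field(v, BinaryMask(np.zeros(v.shape, np.uint8), v.spacing))

    def test_correction_recovers_clean_image(self):
        v, m = self._uniform_brain()
        ramp = np.linspace(0.85, 1.15, 24)[None, :, None] * np.ones_like(v.data)
        biased = Volume(v.data * ramp, v.spacing)
        field = estimate_bias_field(biased, m, order=3)
        fixed = correct_bias(biased, field)
        inside = m.data.astype(bool)
        rel = np.abs(fixed.data[inside] - v.data[inside]) / v.data[inside]
        assert rel.max() < 0.02

    def test_correction_reduces_cv(self, rng):
        v, m = self._uniform_brain()
        ramp = np.linspace(0.8, 1.2, 8)[None, None, :] * np.ones_like(v.data)
        biased = Volume(v.data * ramp * (1 + 0.005 * rng.normal(size=v.shape)),
                        v.spacing)
        field = estimate_bias_field(biased, m, order=3)
        fixed = correct_bias(biased, field)
        inside = m.data.astype(bool)
        cv = lambda a: a.std() / a.mean()
        assert cv(fixed.data[inside]) < cv(biased.data[inside])

    def test_identity_field(self, random_volume):
        field = Volume(np.ones(random_volume.shape), random_volume.spacing)
        out = correct_bias(random_volume, field)
        np.testing.assert_array_equal(out.data, random_volume.data)


class TestApplyMask:
    def test_all_ones_identity(self, random_volume):
        m = BinaryMask(np.ones(random_volume.shape, np.uint8), random_volume.spacing)
        np.testing.assert_array_equal(apply_mask(random_volume, m).data,
                                      random_volume.data)

    def test_all_zeros(self, random_volume):
        m = BinaryMask(np.zeros(random_volume.shape, np.uint8), random_volume.spacing)
        assert np.all(apply_mask(random_volume, m).data == 0)

    def test_nothing_outside_brain(self, clean_spec):
        case = make_phantom(clean_spec)
        stripped = apply_mask(case.t1, case.brain_truth)
        outside = ~case.brain_truth.data.astype(bool)
        assert np.all(stripped.data[outside] == 0)
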