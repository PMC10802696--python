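"""Warping, loss terms, analytic gradients and the variational fit."""

import numpy as np
import pytest

from alignedstrain.phantom import PhantomSpec, render_phantom
from alignedstrain.registration import (
    DisplacementFieldSet,
    KeyFrameRegistration,
    LossWeights,
    RegistrationConfig,
    _smoothness_value_grad,
    _soft_dice_value_grad,
    _ssim_value_grad,
    compose_fields,
    dice_loss,
    fit_registration,
    smoothness,
    ssim_slice,
    ssim_volume_loss,
    total_loss,
    warp,
)

from conftest import small_spec


def smooth_random_field(shape, amplitude, seed=0):
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    f = rng.normal(0, 1, shape + (2,))
    for c in range(2):
        f[..., c] = gaussian_filter(f[..., c], sigma=2.0)
    return amplitude * f / np.abs(f).max()


class TestWarp:
    def test_zero_field_is_identity(self):
        rng = np.random.default_rng(0)
        vol = rng.normal(size=(3, 12, 12))
        out = warp(vol, np.zeros(vol.shape + (2,)))
        assert np.allclose(out, vol)

    def test_constant_integer_shift_with_border_clamp(self):
        rng = np.random.default_rng(1)
        img = rng.normal(size=(10, 10))
        field = np.zeros((10, 10, 2))
        field[..., 1] = 2.0  # sample two columns to the right
        out = warp(img, field)
        assert np.allclose(out[:, :-2], img[:, 2:])
        assert np.allclose(out[:, -2:], img[:, -1:][:, [0, 0]])

    def test_matches_direct_bilinear_oracle(self):
        rng = np.random.default_rng(2)
        img = rng.normal(size=(16, 16))
        field = smooth_random_field((16, 16), amplitude=2.5, seed=3)
        out = warp(img, field)
        # independent per-pixel bilinear interpolation with border clamping
        expected = np.empty_like(img)
        for i in range(16):
            for j in range(16):
                y = np.clip(i + field[i, j, 0], 0, 15)
                x = np.clip(j + field[i, j, 1], 0, 15)
                y0, x0 = int(np.floor(y)), int(np.floor(x))
                y1, x1 = min(y0 + 1, 15), min(x0 + 1, 15)
                wy, wx = y - y0, x - x0
                expected[i, j] = (
                    img[y0, x0] * (1 - wy) * (1 - wx)
                    + img[y0, x1] * (1 - wy) * wx
                    + img[y1, x0] * wy * (1 - wx)
                    + img[y1, x1] * wy * wx
                )
        assert np.allclose(out, expected, atol=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            warp(np.zeros((4, 4)), np.zeros((5, 5, 2)))


class TestSsim:
    def test_identical_slices_give_one(self):
        rng = np.random.default_rng(0)
        f = rng.normal(size=(20, 20))
        assert ssim_slice(f, f) == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        f = rng.normal(size=(20, 20))
        m = f + rng.normal(0, 0.3, f.shape)
        assert ssim_slice(f, m) == pytest.approx(ssim_slice(m, f), rel=1e-12)

    def test_constant_slices_closed_form(self):
        # mu_f=0, mu_m=1, all (co)variances zero: eps1*eps2/((1+eps1)*eps2)
        f = np.zeros((15, 15))
        m = np.ones((15, 15))
        eps1, eps2 = 0.02, 0.05
        val = ssim_slice(f, m, eps1=eps1, eps2=eps2)
        assert val == pytest.approx(eps1 / (1 + eps1))

    def test_window_larger_than_slice_rejected(self):
        with pytest.raises(ValueError, match="window"):
            ssim_slice(np.zeros((5, 5)), np.zeros((5, 5)), window=7)

    def test_bounded_above_by_one(self):
        rng = np.random.default_rng(2)
        for seed in range(5):
            f = rng.normal(size=(16, 16))
            m = rng.normal(size=(16, 16))
            assert ssim_slice(f, m) <= 1.0 + 1e-12

    def test_volume_loss_zero_for_identical(self):
        rng = np.random.default_rng(3)
        vol = rng.normal(size=(4, 16, 16))
        assert ssim_volume_loss(vol, vol) == pytest.approx(0.0, abs=1e-12)

    def test_single_slice_volume_reduces_to_slice_form(self):
        rng = np.random.default_rng(4)
        f = rng.normal(size=(16, 16))
        m = rng.normal(size=(16, 16))
        assert ssim_volume_loss(f[None], m[None]) == pytest.approx(1 - ssim_slice(f, m))

    def test_loss_increases_with_noise(self):
        # Monte-Carlo: more noise on the moved volume raises the loss
        rng = np.random.default_rng(5)
        base = rng.normal(size=(2, 24, 24))
        low, high = [], []
        for seed in range(20):
            r = np.random.default_rng(seed)
            low.append(ssim_volume_loss(base, base + r.normal(0, 0.1, base.shape)))
            high.append(ssim_volume_loss(base, base + r.normal(0, 0.5, base.shape)))
        assert np.mean(high) > np.mean(low)


class TestDice:
    def test_identical_masks_zero(self):
        m = np.zeros((6, 6), bool)
        m[2:4, 2:4] = True
        assert dice_loss(m, m) == pytest.approx(0.0)

    def test_disjoint_masks_closed_form(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[:2, :3] = True  # A = 6
        b[5:, 5:] = True  # B = 9
        assert dice_loss(a, b) == pytest.approx(1 - 1 / (6 + 9 + 1))

    def test_half_overlapping_squares(self):
        a = np.zeros((4, 6), bool)
        b = np.zeros((4, 6), bool)
        a[1:3, 1:3] = True
        b[1:3, 2:4] = True  # A = B = 4, intersection 2
        assert dice_loss(a, b) == pytest.approx(1 - 5 / 9)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            dice_loss(np.arange(4).reshape(2, 2), np.zeros((2, 2)))


class TestSmoothness:
    def test_constant_field_zero(self):
        f = np.full((3, 8, 8, 2), 1.7)
        assert smoothness(f) == 0.0

    def test_translation_invariance(self):
        f = smooth_random_field((3, 10, 10), amplitude=2.0, seed=0)
        assert smoothness(f + 3.2) == pytest.approx(smoothness(f))

    def test_linear_field_hand_count(self):
        # slope a along each axis: every forward difference equals a
        n = 4
        a = 0.5
        zz, yy, xx = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        f = np.stack([a * (zz + yy + xx)] * 2, axis=-1)
        # per axis: (n-1)*n*n positions x 2 components, each difference a^2
        expected = 3 * (n - 1) * n * n * 2 * a**2
        assert smoothness(f) == pytest.approx(expected)


class TestAnalyticGradients:
    def test_ssim_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        f = rng.normal(size=(18, 18))
        m = f + rng.normal(0, 0.4, f.shape)
        val, grad = _ssim_value_grad(f, m, 5, None, None, 4.0)
        h = 1e-6
        # interior pixels: the reflect-padding adjoint is exact there
        for (i, j) in [(8, 8), (9, 6), (7, 10)]:
            mp = m.copy()
            mp[i, j] += h
            vp, _ = _ssim_value_grad(f, mp, 5, None, None, 4.0)
            assert (vp - val) / h == pytest.approx(grad[i, j], rel=1e-3)

    def test_soft_dice_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        sf = (rng.random((6, 6)) > 0.5).astype(float)
        w = rng.random((6, 6))
        val, grad = _soft_dice_value_grad(sf, w)
        h = 1e-7
        for (i, j) in [(0, 0), (3, 4), (5, 5)]:
            wp = w.copy()
            wp[i, j] += h
            vp, _ = _soft_dice_value_grad(sf, wp)
            assert (vp - val) / h == pytest.approx(grad[i, j], rel=1e-4)

    def test_smoothness_gradient_matches_finite_differences(self):
        u = smooth_random_field((2, 6, 6), amplitude=1.0, seed=2)
        val, grad = _smoothness_value_grad(u, "mean")
        h = 1e-7
        idx = (1, 3, 2, 0)
        up = u.copy()
        up[idx] += h
        vp, _ = _smoothness_value_grad(up, "mean")
        assert (vp - val) / h == pytest.approx(grad[idx], rel=1e-4)


class TestTotalLoss:
    def _inputs(self):
        spec = small_spec()
        ph = render_phantom(spec)
        kf = ph.keyframes
        vols = {k: ph.cine.values[kf[k]] for k in kf.as_dict()}
        masks = {k: ph.masks.labels[kf[k]] == 2 for k in kf.as_dict()}
        shape = next(iter(vols.values())).shape
        zero = np.zeros(shape + (2,))
        fields = DisplacementFieldSet(
            composed={k: zero.copy() for k in ("MS", "ES", "PF", "MD", "ED")},
            sequential={p: zero.copy() for p in (("ED", "MS"), ("MS", "ES"), ("ES", "PF"), ("PF", "MD"), ("MD", "ED"))},
        )
        return vols, masks, fields

    def test_zero_fields_identical_volumes_give_zero(self):
        vols, masks, fields = self._inputs()
        same_vols = {k: vols["ED"] for k in vols}
        same_masks = {k: masks["ED"] for k in masks}
        total, breakdown = total_loss(same_vols, same_masks, fields)
        assert total == pytest.approx(0.0, abs=1e-9)

    def test_linear_in_weights(self):
        vols, masks, fields = self._inputs()
        w1 = LossWeights(1.0, 1.0, 1.0, 0.5)
        w2 = LossWeights(2.0, 2.0, 2.0, 1.0)
        t1, _ = total_loss(vols, masks, fields, w1)
        t2, _ = total_loss(vols, masks, fields, w2)
        assert t2 == pytest.approx(2 * t1)

    def test_missing_field_rejected(self):
        vols, masks, fields = self._inputs()
        del fields.sequential[("MS", "ES")]
        with pytest.raises(ValueError, match="missing sequential field"):
            total_loss(vols, masks, fields)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(-1.0, 1.0, 1.0, 0.1)
        with pytest.raises(ValueError):
            LossWeights(0.0, 0.0, 0.0, 0.1)


QUICK_CONFIG = RegistrationConfig(pyramid=(2, 1), iterations=(40, 30))


class TestFit:
    def test_static_phantom_keeps_near_zero_fields(self):
        spec = small_spec(contraction_profile=np.ones(20), noise_sd=1.0, seed=3)
        ph = render_phantom(spec)
        res = fit_registration(ph.cine, ph.masks, ph.keyframes, config=QUICK_CONFIG)
        for f in list(res.fields.composed.values()) + list(res.fields.sequential.values()):
            assert np.mean(np.linalg.norm(f, axis=-1)) < 0.1

    def test_fit_is_deterministic(self):
        spec = small_spec(noise_sd=1.0, seed=4)
        ph = render_phantom(spec)
        a = fit_registration(ph.cine, ph.masks, ph.keyframes, config=QUICK_CONFIG)
        b = fit_registration(ph.cine, ph.masks, ph.keyframes, config=QUICK_CONFIG)
        for k in a.fields.composed:
            assert np.array_equal(a.fields.composed[k], b.fields.composed[k])

    def test_fitted_fields_reduce_total_loss(self, quiet_phantom):
        ph = quiet_phantom
        res = fit_registration(ph.cine, ph.masks, ph.keyframes, config=QUICK_CONFIG)
        kf = ph.keyframes
        vols = {k: ph.cine.values[kf[k]].astype(float) for k in kf.as_dict()}
        masks = {k: ph.masks.labels[kf[k]] == 2 for k in kf.as_dict()}
        shape = vols["ED"].shape
        zero_fields = DisplacementFieldSet(
            composed={k: np.zeros(shape + (2,)) for k in res.fields.composed},
            sequential={p: np.zeros(shape + (2,)) for p in res.fields.sequential},
        )
        before, _ = total_loss(vols, masks, zero_fields)
        after, _ = total_loss(vols, masks, res.fields)
        assert after <= before

    def test_dice_improves_over_identity_on_moving_phantom(self, quiet_phantom):
        res = fit_registration(
            quiet_phantom.cine, quiet_phantom.masks, quiet_phantom.keyframes, config=QUICK_CONFIG
        )
        table = res.dice_table()
        moving = table[table.dice_identity < 0.999]
        assert not moving.empty
        assert np.all(moving.dice_warped >= moving.dice_identity)

    def test_predict_fields_round_trip(self, quiet_phantom):
        res = fit_registration(
            quiet_phantom.cine, quiet_phantom.masks, quiet_phantom.keyframes, config=QUICK_CONFIG
        )
        fields = res.predict_fields()
        assert set(fields.composed) == {"MS", "ES", "PF", "MD", "ED"}
        assert set(fields.sequential) == {
            ("ED", "MS"), ("MS", "ES"), ("ES", "PF"), ("PF", "MD"), ("MD", "ED")
        }
        again = res.predict_fields()
        for k in fields.composed:
            assert np.array_equal(fields.composed[k], again.composed[k])

    def test_summary_mentions_all_pairs(self, quiet_phantom):
        res = fit_registration(
            quiet_phantom.cine, quiet_phantom.masks, quiet_phantom.keyframes, config=QUICK_CONFIG
        )
        text = res.summary()
        for tag in ("k2k:ED-MS", "k2ed:ES", "Dice"):
            assert tag in text


class TestComposeFields:
    def test_composing_with_zero_is_identity(self):
        f = smooth_random_field((2, 12, 12), amplitude=1.5, seed=5)
        z = np.zeros_like(f)
        assert np.allclose(compose_fields(z, f), f)
        assert np.allclose(compose_fields(f, z), f)

    def test_analytic_cycle_drift_is_tiny(self, quiet_spec, quiet_phantom):
        fields = DisplacementFieldSet.from_analytic(quiet_spec, quiet_phantom.keyframes)
        myo = quiet_phantom.masks.labels[quiet_phantom.keyframes.ed] == 2
        drift = fields.cycle_drift()
        assert np.median(drift[myo]) < 0.05
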