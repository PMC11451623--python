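import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from t1epi.config import default_protocol
from t1epi.distortion import (
    FieldMap,
    WarpSpec,
    apply_distortion,
    estimate_field_from_pair,
    match_echo_spacing,
    synthesize_warp_level,
    unwarp_distortion,
)
from t1epi.io import ImageVolume
from t1epi.phantom import generate_field_maps, generate_phantom


def _bump_volume(n=64, width=8.0):
    y = np.arange(n)
    line = np.exp(-(((y - n / 2) / width) ** 2))
    data = np.broadcast_to(line[None, :, None], (4, n, 4)).copy()
    return ImageVolume(data, np.eye(4), pe_axis=1)


@pytest.fixture(scope="module")
def warped_pair():
    """Textureless smooth phantom warped at both PE polarities by a known
    smooth field with a 4-voxel maximum displacement."""
    shape = (48, 48, 48)
    ph = generate_phantom(3, shape)
    img_data = gaussian_filter(ph.M0, 1.5)
    b0, _ = generate_field_maps(7, shape, peak_hz=30.0, smooth_frac=0.3)
    esp, npe = 2.0, shape[1]
    raw_disp = np.abs(b0.data * esp * 1e-3 * npe).max()
    field = FieldMap(b0.data * (4.0 / raw_disp))
    img = ImageVolume(img_data, np.eye(4))
    vp = apply_distortion(img, field, esp, +1)
    vm = apply_distortion(img, field, esp, -1)
    return img, field, vp, vm, esp, npe, ph.support


class TestApplyDistortion:
    def test_zero_field_identity(self):
        vol = _bump_volume()
        out = apply_distortion(vol, FieldMap(np.zeros(vol.shape)), 0.5, +1)
        assert np.allclose(out.data, vol.data, atol=1e-12)

    @pytest.mark.parametrize("polarity", [+1, -1])
    def test_uniform_field_uniform_shift(self, polarity):
        n = 100
        y = np.arange(n)
        line = np.exp(-(((y - 50) / 8.0) ** 2))
        vol = ImageVolume(np.broadcast_to(line[None, :, None], (3, n, 3)).copy(),
                          np.eye(4))
        # 10 Hz * 0.5 ms * 100 = 0.5 voxels
        out = apply_distortion(vol, FieldMap(np.full(vol.shape, 10.0)), 0.5,
                               polarity, npe=100)
        expected = np.exp(-(((y - polarity * 0.5 - 50) / 8.0) ** 2))
        assert np.max(np.abs(out.data[0, :, 0] - expected)) < 2e-3

    def test_point_lands_at_predicted_coordinate_and_conserves_mass(self):
        n = 64
        data = np.zeros((3, n, 3))
        data[1, 30, 1] = 1.0
        data = gaussian_filter(data, (0, 2.0, 0))
        vol = ImageVolume(data, np.eye(4))
        shift_true = 2.75  # uniform field: analytic displacement
        hz = shift_true / (0.5e-3 * n)
        out = apply_distortion(vol, FieldMap(np.full(vol.shape, hz)), 0.5, +1)
        y = np.arange(n)
        centroid = np.sum(y * out.data[1, :, 1]) / np.sum(out.data[1, :, 1])
        assert centroid == pytest.approx(30 + shift_true, abs=0.1)
        assert np.sum(out.data) == pytest.approx(np.sum(data), rel=1e-6)

    def test_excessive_displacement_rejected(self):
        vol = _bump_volume(n=32)
        with pytest.raises(ValueError, match="half the PE"):
            apply_distortion(vol, FieldMap(np.full(vol.shape, 2000.0)), 0.5, +1)

    def test_unwarp_inverts_apply_within_interpolation_error(self, warped_pair):
        img, field, vp, _, esp, _, support = warped_pair
        back = unwarp_distortion(vp, field, esp, +1)
        rel = (np.sqrt(np.mean((back.data[support] - img.data[support]) ** 2))
               / np.sqrt(np.mean(img.data[support] ** 2)))
        assert rel < 0.01


class TestEstimateField:
    def test_identical_inputs_zero_field(self):
        vol = _bump_volume()
        est = estimate_field_from_pair(vol, vol, 0.5)
        assert np.max(np.abs(est.data)) < 1e-9

    def test_recovers_known_field(self, warped_pair):
        img, field, vp, vm, esp, npe, support = warped_pair
        est = estimate_field_from_pair(vp, vm, esp)
        truth = field.displacement_voxels(esp, npe)
        got = est.displacement_voxels(esp, npe)
        rmse = np.sqrt(np.mean((got[support] - truth[support]) ** 2))
        assert rmse < 0.5

    def test_antisymmetric_in_input_order(self, warped_pair):
        _, _, vp, vm, esp, _, _ = warped_pair
        fwd = estimate_field_from_pair(vp, vm, esp, scales=(4.0, 2.0), n_iter=10)
        rev = estimate_field_from_pair(vm, vp, esp, scales=(4.0, 2.0), n_iter=10)
        assert np.array_equal(fwd.data, -rev.data)

    def test_pair_correction_beats_distorted_input(self, warped_pair):
        """The corrected image (mean of the two unwarped polarities) is
        at least 5x closer to the undistorted phantom than the distorted
        input, and both unwarped inputs beat the raw distorted one."""
        img, field, vp, vm, esp, npe, support = warped_pair
        est = estimate_field_from_pair(vp, vm, esp)
        up = unwarp_distortion(vp, est, esp, +1)
        um = unwarp_distortion(vm, est, esp, -1)
        corrected = 0.5 * (up.data + um.data)

        def rmse(x):
            return np.sqrt(np.mean((x[support] - img.data[support]) ** 2))

        assert rmse(corrected) <= rmse(vp.data) / 5.0
        assert rmse(0.5 * (up.data + um.data)) < min(rmse(vp.data), rmse(vm.data))

    def test_linear_response_to_field_amplitude(self, warped_pair):
        img, field, _, _, esp, npe, support = warped_pair
        half = FieldMap(field.data * 0.5)
        vp_h = apply_distortion(img, half, esp, +1)
        vm_h = apply_distortion(img, half, esp, -1)
        vp_f = apply_distortion(img, field, esp, +1)
        vm_f = apply_distortion(img, field, esp, -1)
        e_h = estimate_field_from_pair(vp_h, vm_h, esp).data[support]
        e_f = estimate_field_from_pair(vp_f, vm_f, esp).data[support]
        t_h = (half.data * 0.5)[support]  # regress each on its own truth
        slope_h = np.sum(e_h * half.data[support]) / np.sum(half.data[support] ** 2)
        slope_f = np.sum(e_f * field.data[support]) / np.sum(field.data[support] ** 2)
        assert slope_f / slope_h == pytest.approx(1.0, abs=0.1)

    def test_no_overlap_rejected(self):
        a = ImageVolume(np.zeros((4, 4, 4)), np.eye(4))
        with pytest.raises(ValueError, match="overlap"):
            estimate_field_from_pair(a, a, 0.5)


class TestSynthesizeWarp:
    def test_lambda_zero_identity(self, warped_pair):
        img, field, _, _, esp, _, _ = warped_pair
        out = synthesize_warp_level(img, field, WarpSpec(lam=0.0, esp_eff_ms=esp))
        assert np.array_equal(out.data, img.data)

    def test_lambda_one_reproduces_full_distortion(self, warped_pair):
        img, field, vp, _, esp, _, _ = warped_pair
        out = synthesize_warp_level(img, field, WarpSpec(lam=1.0, esp_eff_ms=esp,
                                                         polarity=+1))
        assert np.allclose(out.data, vp.data, atol=1e-12)

    def test_half_warp_twice_approximates_full(self, warped_pair):
        img, field, vp, _, esp, _, support = warped_pair
        spec = WarpSpec(lam=0.5, esp_eff_ms=esp, polarity=+1)
        once = synthesize_warp_level(img, field, spec)
        twice = synthesize_warp_level(once, field, spec)
        # compare in displacement-equivalent units via the intensity gradient
        grad = np.abs(np.gradient(img.data, axis=1))
        denom = np.maximum(grad[support].mean(), 1e-9)
        err = np.abs(twice.data[support] - vp.data[support]).mean() / denom
        assert err < 0.05


class TestMatchEchoSpacing:
    def test_already_matched_returns_default(self):
        p = default_protocol()
        matched, report = match_echo_spacing(p, p.esp_eff, p.N[1])
        assert matched.seg == p.seg
        assert report["residual_rel"] < 1e-12

    def test_double_spacing_halves_segmentation(self):
        p = default_protocol()
        matched, report = match_echo_spacing(p, 2 * p.esp_eff, p.N[1])
        assert matched.seg == p.seg // 2
        assert matched.esp_eff == pytest.approx(2 * p.esp_eff)

    def test_infeasible_tolerance_lists_candidates(self):
        p = default_protocol()
        with pytest.raises(ValueError, match="nearest"):
            match_echo_spacing(p, 1.37 * p.esp_eff, p.N[1], tol=1e-6)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            match_echo_spacing(default_protocol(), -1.0, 100)
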