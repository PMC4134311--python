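import numpy as np
import pytest
from hypothesis import given, strategies as st

from icanet.preprocess import (
    MotionParams,
    detrend_voxelwise,
    discard_initial,
    motion_check,
    nuisance_regression,
    preprocess_subject,
    smooth_gaussian,
)
from icanet.volume import Grid, Volume4D


def _vol(data, voxel_mm=3.0, tr_s=2.0):
    data = np.asarray(data, dtype=np.float32)
    grid = Grid(origin=(0.0, 0.0, 0.0), voxel_mm=voxel_mm, shape=data.shape[:3])
    return Volume4D(data=data, grid=grid, tr_s=tr_s)


class TestDiscardInitial:
    def test_210_minus_2_is_208(self):
        vol = _vol(np.zeros((2, 2, 2, 210)))
        assert discard_initial(vol, 2).n_volumes == 208

    def test_zero_is_identity(self):
        vol = _vol(np.arange(2 * 2 * 2 * 5, dtype=float).reshape(2, 2, 2, 5))
        out = discard_initial(vol, 0)
        assert np.array_equal(out.data, vol.data)

    def test_empty_result_forbidden(self):
        vol = _vol(np.zeros((2, 2, 2, 2)))
        with pytest.raises(ValueError):
            discard_initial(vol, 2)

    def test_drops_leading_volumes(self):
        data = np.zeros((1, 1, 1, 5))
        data[0, 0, 0] = [10, 20, 1, 2, 3]
        out = discard_initial(_vol(data), 2)
        assert np.array_equal(out.data[0, 0, 0], [1, 2, 3])


class TestMotionCheck:
    def test_all_zero_passes(self):
        params = MotionParams(np.zeros((5, 3)), np.zeros((5, 3)))
        check = motion_check(params, 3.0)
        assert check.passed
        assert check.max_excursion_mm == 0.0

    def test_translation_over_half_voxel_fails(self):
        trans = np.zeros((5, 3))
        trans[2, 0] = 1.6
        check = motion_check(MotionParams(trans, np.zeros((5, 3))), 3.0)
        assert not check.passed
        assert check.threshold_mm == pytest.approx(1.5)

    def test_half_degree_rotation_passes(self):
        rot = np.zeros((5, 3))
        rot[1, 2] = 0.5
        check = motion_check(MotionParams(np.zeros((5, 3)), rot), 3.0)
        # Arc length at 65 mm: 65 * pi * 0.5 / 180 = 0.567 mm < 1.5 mm.
        assert check.max_excursion_mm == pytest.approx(0.567, abs=1e-3)
        assert check.passed

    def test_tsv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        params = MotionParams(rng.standard_normal((4, 3)), rng.standard_normal((4, 3)))
        path = tmp_path / "motion.tsv"
        params.to_tsv(path)
        back = MotionParams.from_tsv(path)
        assert np.allclose(back.translations_mm, params.translations_mm, atol=1e-6)
        assert np.allclose(back.rotations_deg, params.rotations_deg, atol=1e-6)


class TestDetrend:
    def test_pure_line_becomes_its_mean(self):
        a, b, nt = 5.0, 0.3, 20
        t = np.arange(nt)
        data = np.broadcast_to(a + b * t, (2, 2, 2, nt)).copy()
        out = detrend_voxelwise(_vol(data))
        assert np.allclose(out.data, a + b * t.mean(), atol=1e-4)

    def test_sine_survives_line_removal(self):
        # Regression oracle: slope removal is linear, so detrending
        # (sine + line) must equal the analytically detrended sine plus the
        # line's mean, and correlate > 0.999 with that target.
        nt = 100
        t = np.arange(nt, dtype=float)
        tc = t - t.mean()
        sine = np.sin(2 * np.pi * t / 25.0)
        data = (sine + 0.1 * t)[None, None, None, :]
        out = detrend_voxelwise(_vol(data))
        expected = sine - ((sine @ tc) / (tc @ tc)) * tc + (0.1 * t).mean()
        assert np.allclose(out.data[0, 0, 0], expected, atol=1e-4)
        resid = out.data[0, 0, 0] - out.data[0, 0, 0].mean()
        target = expected - expected.mean()
        assert np.corrcoef(resid, target)[0, 1] > 0.999

    def test_mean_preserved(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((3, 3, 3, 30))
        out = detrend_voxelwise(_vol(data))
        assert np.allclose(out.data.mean(axis=-1), data.mean(axis=-1), atol=1e-5)

    @given(st.integers(0, 2**31 - 1))
    def test_idempotence(self, seed):
        rng = np.random.default_rng(seed)
        vol = _vol(rng.standard_normal((2, 2, 2, 15)))
        once = detrend_voxelwise(vol)
        twice = detrend_voxelwise(once)
        assert np.allclose(twice.data, once.data, atol=1e-4)


class TestSmoothGaussian:
    def test_zero_fwhm_is_identity(self):
        rng = np.random.default_rng(2)
        vol = _vol(rng.standard_normal((4, 4, 4, 3)))
        out = smooth_gaussian(vol, 0.0)
        assert np.array_equal(out.data, vol.data)

    def test_impulse_centre_equals_kernel_weight(self):
        # Oracle: sampled-Gaussian kernel evaluated directly, separable cube.
        fwhm, voxel = 6.0, 3.0
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2))) / voxel
        radius = int(4.0 * sigma + 0.5)
        k = np.exp(-np.arange(-radius, radius + 1) ** 2 / (2 * sigma**2))
        k /= k.sum()
        expected = float(k[radius] ** 3)

        data = np.zeros((15, 15, 15, 1), dtype=np.float32)
        data[7, 7, 7, 0] = 1.0
        out = smooth_gaussian(_vol(data, voxel_mm=voxel), fwhm)
        assert out.data[7, 7, 7, 0] == pytest.approx(expected, abs=1e-6)

    def test_mass_conserved_for_interior_impulse(self):
        data = np.zeros((21, 21, 21, 1), dtype=np.float32)
        data[10, 10, 10, 0] = 1.0
        out = smooth_gaussian(_vol(data), 6.0)
        assert out.data.sum() == pytest.approx(1.0, rel=1e-6)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            smooth_gaussian(_vol(np.zeros((2, 2, 2, 1))), -1.0)


class TestNuisanceRegression:
    @staticmethod
    def _masks(shape):
        wm = np.zeros(shape, dtype=bool)
        csf = np.zeros(shape, dtype=bool)
        wm[0, 0, 0] = True
        csf[-1, -1, -1] = True
        return wm, csf

    def test_pure_wm_signal_removed_entirely(self):
        nt = 30
        rng = np.random.default_rng(3)
        sig = rng.standard_normal(nt)
        data = np.broadcast_to(sig, (3, 3, 3, nt)).copy()
        wm, csf = self._masks((3, 3, 3))
        # Distinct CSF series so the two covariates are not collinear.
        data[csf] = rng.standard_normal(nt)
        out, series = nuisance_regression(_vol(data), wm, csf)
        interior = out.data[1, 1, 1]
        assert np.allclose(interior, 0.0, atol=1e-4)

    def test_residual_orthogonal_to_regressors(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((4, 4, 4, 40))
        wm, csf = self._masks((4, 4, 4))
        out, series = nuisance_regression(_vol(data), wm, csf)
        flat = out.data.reshape(-1, 40).astype(np.float64)
        for col in series.columns:
            dots = flat @ series[col].to_numpy()
            assert np.max(np.abs(dots)) < 1e-6

    def test_single_voxel_masks_give_exact_covariates(self):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((3, 3, 3, 20))
        wm, csf = self._masks((3, 3, 3))
        _, series = nuisance_regression(_vol(data), wm, csf)
        assert np.allclose(series["WM"], data[0, 0, 0], atol=1e-6)
        assert np.allclose(series["CSF"], data[-1, -1, -1], atol=1e-6)

    def test_planted_network_preserved_nuisance_removed(self):
        nt = 60
        rng = np.random.default_rng(6)
        net_tc = rng.standard_normal(nt)
        nuis_tc = rng.standard_normal(nt)
        data = np.zeros((5, 5, 5, nt))
        data[2, 2, 2] = net_tc
        wm, csf = self._masks((5, 5, 5))
        data[wm] += nuis_tc
        data[csf] += rng.standard_normal(nt)
        out, series = nuisance_regression(_vol(data), wm, csf)
        resid_net = out.data[2, 2, 2]
        assert np.corrcoef(resid_net, net_tc)[0, 1] > 0.95
        wm_resid = out.data[0, 0, 0] @ series["WM"].to_numpy()
        assert abs(wm_resid) < 1e-6

    def test_collinear_covariates_drop_csf_with_warning(self):
        nt = 20
        sig = np.sin(np.linspace(0, 6, nt))
        data = np.zeros((3, 3, 3, nt))
        wm, csf = self._masks((3, 3, 3))
        data[wm] = sig
        data[csf] = 2.0 * sig + 1.0
        with pytest.warns(UserWarning, match="collinear"):
            _, series = nuisance_regression(_vol(data), wm, csf)
        assert list(series.columns) == ["WM"]

    def test_empty_mask_rejected(self):
        data = np.zeros((3, 3, 3, 10))
        wm = np.zeros((3, 3, 3), dtype=bool)
        csf = np.zeros((3, 3, 3), dtype=bool)
        csf[0, 0, 0] = True
        with pytest.raises(ValueError, match="WM"):
            nuisance_regression(_vol(data), wm, csf)


class TestPreprocessSubject:
    def test_motion_failure_raises(self):
        rng = np.random.default_rng(7)
        vol = _vol(rng.standard_normal((3, 3, 3, 10)))
        wm = np.zeros((3, 3, 3), dtype=bool)
        wm[0, 0, 0] = True
        csf = np.zeros((3, 3, 3), dtype=bool)
        csf[2, 2, 2] = True
        trans = np.zeros((8, 3))
        trans[3, 1] = 2.0
        motion = MotionParams(trans, np.zeros((8, 3)))
        with pytest.raises(ValueError, match="motion QC"):
            preprocess_subject(vol, wm, csf, n_discard=2, motion=motion)

    def test_chain_runs_and_trims(self):
        rng = np.random.default_rng(8)
        vol = _vol(rng.standard_normal((4, 4, 4, 12)))
        wm = np.zeros((4, 4, 4), dtype=bool)
        wm[0, 0, 0] = True
        csf = np.zeros((4, 4, 4), dtype=bool)
        csf[3, 3, 3] = True
        out = preprocess_subject(vol, wm, csf, n_discard=2, fwhm_mm=6.0)
        assert out.n_volumes == 10
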