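"""Kinetic-model fitting: recovery, uncertainties and edge cases."""

import numpy as np
import pytest

from vepcasl import (FitResult, KineticParams, Priors, fit_voxel, fit_volume,
                     voxel_signal, weighted_bat)
from vepcasl.fitting import ComponentFit, _basis, _readout_times


class TestSingleComponent:
    def test_noiseless_recovery(self, timing):
        y = voxel_signal([KineticParams(60.0, 1.0)], timing)
        fit = fit_voxel(y, timing, noise_sd=1e-6 * y.max())
        assert fit.components[0].cbf == pytest.approx(60.0, rel=1e-3)
        assert fit.components[0].bat == pytest.approx(1.0, abs=1e-3)
        assert fit.converged

    @pytest.mark.parametrize("cbf,bat", [(30.0, 0.6), (60.0, 1.3), (90.0, 1.8)])
    def test_noisy_recovery_within_bounds(self, timing, cbf, bat):
        # documented error bounds at SNR ~ 50 per PLD: CBF within 10%,
        # BAT within 0.1 s (averaged over realizations)
        rng = np.random.default_rng(42)
        y0 = voxel_signal([KineticParams(cbf, bat)], timing)
        sigma = y0.max() / 50.0
        ests = []
        for _ in range(20):
            y = y0 + rng.normal(0.0, sigma, y0.size)
            fit = fit_voxel(y, timing, noise_sd=sigma)
            ests.append((fit.components[0].cbf, fit.components[0].bat))
        ests = np.array(ests)
        assert abs(ests[:, 0].mean() - cbf) / cbf < 0.10
        assert abs(ests[:, 1].mean() - bat) < 0.10

    def test_zero_signal_returns_zero_flow(self, timing):
        fit = fit_voxel(np.zeros(6), timing)
        assert fit.total_cbf == 0.0
        assert np.isinf(fit.components[0].cbf_var)

    def test_slice_timing_is_honoured(self, timing):
        p = KineticParams(60.0, 1.0)
        y = voxel_signal([p], timing, slice_index=12)
        fit_right = fit_voxel(y, timing, slice_index=12,
                              noise_sd=1e-6 * y.max())
        fit_wrong = fit_voxel(y, timing, slice_index=0,
                              noise_sd=1e-6 * y.max())
        err_right = abs(fit_right.components[0].bat - 1.0)
        err_wrong = abs(fit_wrong.components[0].bat - 1.0)
        assert err_right < 1e-3 < err_wrong

    def test_laplace_variance_close_to_linear_theory(self, timing):
        # With BAT pinned by the data, the amplitude variance approaches the
        # fixed-BAT linear value sigma^2 / (g.g); BAT coupling can only
        # inflate it. Allow a factor-4 window around the linear bound.
        cbf, bat, snr = 60.0, 1.0, 100.0
        y0 = voxel_signal([KineticParams(cbf, bat)], timing)
        sigma = y0.max() / snr
        fit = fit_voxel(y0, timing, noise_sd=sigma)
        g = _basis(_readout_times(timing, 0), bat, timing.tau, 1.6, 1.3)
        var_lin = sigma ** 2 / float(g @ g)
        assert var_lin * 0.9 <= fit.components[0].cbf_var <= 4.0 * var_lin

    def test_prior_pulls_bat_when_data_uninformative(self, timing):
        # tiny signal, huge noise: posterior ~ prior
        rng = np.random.default_rng(0)
        y = rng.normal(0.0, 1.0, 6) * 1e-3
        fit = fit_voxel(y, timing, noise_sd=10.0)
        assert fit.components[0].bat == pytest.approx(1.3, abs=0.05)

    def test_noise_refinement_matches_known_sigma(self, timing):
        rng = np.random.default_rng(1)
        y0 = voxel_signal([KineticParams(60.0, 1.0)], timing)
        sigma = y0.max() / 20.0
        cbfs_ref, cbfs_known = [], []
        for _ in range(10):
            y = y0 + rng.normal(0.0, sigma, 6)
            cbfs_ref.append(fit_voxel(y, timing).components[0].cbf)
            cbfs_known.append(
                fit_voxel(y, timing, noise_sd=sigma).components[0].cbf)
        assert np.mean(cbfs_ref) == pytest.approx(np.mean(cbfs_known),
                                                  rel=0.15)

    def test_input_validation(self, timing):
        with pytest.raises(ValueError):
            fit_voxel(np.ones(1), timing)
        with pytest.raises(ValueError):
            fit_voxel(np.ones(5), timing)  # length != number of PLDs
        with pytest.raises(ValueError):
            fit_voxel(np.ones(6), timing, n_components=0)


class TestPerArtery:
    def test_two_rows_fit_independently(self, timing):
        y1 = voxel_signal([KineticParams(40.0, 0.8)], timing)
        y2 = voxel_signal([KineticParams(20.0, 1.6)], timing)
        fit = fit_voxel(np.stack([y1, y2]), timing, noise_sd=1e-6)
        assert fit.components[0].cbf == pytest.approx(40.0, rel=1e-3)
        assert fit.components[1].cbf == pytest.approx(20.0, rel=1e-3)
        assert fit.components[0].bat == pytest.approx(0.8, abs=1e-3)
        assert fit.components[1].bat == pytest.approx(1.6, abs=1e-3)
        assert fit.total_cbf == pytest.approx(60.0, rel=1e-3)

    def test_weighted_bat(self):
        fit = FitResult([ComponentFit(40.0, 0.8, 1.0, 1.0),
                         ComponentFit(20.0, 1.6, 1.0, 1.0)], 1.0, True)
        assert weighted_bat(fit) == pytest.approx((40 * 0.8 + 20 * 1.6) / 60)
        empty = FitResult([ComponentFit(0.0, 1.3, 1.0, 1.0)], 1.0, True)
        assert np.isnan(weighted_bat(empty))


class TestJointModels:
    def test_two_component_summed_fit(self, timing):
        y = voxel_signal([KineticParams(40.0, 0.8),
                          KineticParams(20.0, 1.6)], timing)
        fit = fit_voxel(y, timing, n_components=2, noise_sd=1e-7 * y.max())
        assert fit.total_cbf == pytest.approx(60.0, rel=0.05)
        bats = sorted(c.bat for c in fit.components)
        assert bats[0] == pytest.approx(0.8, abs=0.1)
        assert bats[1] == pytest.approx(1.6, abs=0.15)

    def test_macrovascular_component_recovered(self, timing):
        p = KineticParams(60.0, 1.0, abv=0.01)
        t = timing.tau + np.asarray(timing.plds)
        from vepcasl.kinetic import component_signal
        y = component_signal(t, p, timing.tau)
        fit = fit_voxel(y, timing, include_macrovascular=True,
                        noise_sd=1e-6 * y.max())
        assert fit.components[0].abv == pytest.approx(0.01, abs=0.004)
        assert fit.components[0].cbf == pytest.approx(60.0, rel=0.1)


class TestFitVolume:
    def test_maps_shapes_and_values(self, timing):
        nx, ny, nz = 3, 2, 4
        data = np.zeros((2, 6, nx, ny, nz))
        y1 = voxel_signal([KineticParams(50.0, 1.0)], timing)
        for zi in range(nz):
            y = voxel_signal([KineticParams(50.0, 1.0)], timing,
                             slice_index=zi)
            data[0, :, :, :, zi] = y[:, None, None]
        mask = np.zeros((nx, ny, nz), bool)
        mask[0, 0, 0] = mask[2, 1, 3] = True
        maps = fit_volume(data, timing, mask)
        assert maps["cbf"].shape == (2, nx, ny, nz)
        assert maps["total_cbf"].shape == (nx, ny, nz)
        for idx in [(0, 0, 0), (2, 1, 3)]:
            assert maps["cbf"][(0,) + idx] == pytest.approx(50.0, rel=0.02)
            assert maps["cbf"][(1,) + idx] == pytest.approx(0.0, abs=1.0)
        assert np.isnan(maps["cbf"][0, 1, 1, 1])  # outside the mask

    def test_empty_or_mismatched_mask_raises(self, timing):
        data = np.zeros((6, 2, 2, 2))
        with pytest.raises(ValueError):
            fit_volume(data, timing, np.zeros((2, 2, 2), bool))
        with pytest.raises(ValueError):
            fit_volume(data, timing, np.ones((3, 2, 2), bool))
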