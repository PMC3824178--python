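"""Digital phantom, synthetic acquisition and NIfTI round trips."""

import numpy as np
import pytest

from vepcasl import (AcquisitionTiming, PerfusionSeries,
                     decode_matrix_inversion, make_phantom, synthesize_series)
from vepcasl.phantom import load_volume, save_volume


class TestPhantomStructure:
    def test_deterministic_under_seed(self):
        a = make_phantom(shape=(24, 24, 6), seed=5)
        b = make_phantom(shape=(24, 24, 6), seed=5)
        c = make_phantom(shape=(24, 24, 6), seed=6)
        assert np.array_equal(a.cbf, b.cbf)
        assert not np.array_equal(a.territory_frac, c.territory_frac)

    def test_fractions_partition_the_brain(self, small_phantom):
        ph = small_phantom
        s = ph.territory_frac.sum(axis=0)
        assert np.allclose(s[ph.brain_mask], 1.0)
        assert np.all(s[~ph.brain_mask] == 0.0)

    def test_total_cbf_matches_tissue_content(self, small_phantom):
        ph = small_phantom
        expected = 60.0 * ph.pv_gm + 20.0 * ph.pv_wm
        assert np.allclose(ph.total_cbf, expected)
        assert np.all(ph.total_cbf[~ph.brain_mask] == 0.0)
        assert ph.total_cbf[ph.gm_mask].max() <= 60.0 + 1e-9

    def test_masks_are_disjoint_and_nested(self, small_phantom):
        ph = small_phantom
        assert not np.any(ph.background_mask & ph.brain_mask)
        assert np.all(ph.brain_mask[ph.ventricle_mask])

    def test_bat_range_and_mixed_offset(self, small_phantom):
        ph = small_phantom
        vals = ph.bat[:, ph.brain_mask]
        assert vals.min() >= 0.9
        assert vals.max() <= 0.9 + 0.5 + 0.4 + 1e-9

    def test_invalid_split_raises(self):
        with pytest.raises(ValueError):
            make_phantom(shape=(8, 8, 4), mixed_split=1.0)


@pytest.fixture(scope="module")
def noiseless():
    ph = make_phantom(shape=(32, 32, 8), seed=0)
    series, truth = synthesize_series(
        ph, "vepcasl", AcquisitionTiming(n_slices=8), snr=np.inf, seed=0)
    return ph, series, truth


class TestSynthesis:
    def test_decode_round_trip_identity(self, noiseless):
        # noiseless synthetic data -> matrix-inversion decoding recovers the
        # sensitivity-weighted per-artery Delta-M fields exactly
        ph, series, truth = noiseless
        dec = decode_matrix_inversion(series.averaged(),
                                      truth["encoding_matrix"])
        expected = truth["delta_m"] * ph.sensitivity
        assert np.allclose(dec.components, expected, atol=1e-10)
        assert np.allclose(dec.static, truth["static"] * ph.sensitivity,
                           atol=1e-10)

    def test_pcasl_pairwise_equals_summed_arteries(self):
        ph = make_phantom(shape=(24, 24, 6), seed=0)
        series, truth = synthesize_series(
            ph, "pcasl", AcquisitionTiming(n_slices=6), snr=np.inf, seed=0)
        perf = series.pairwise_subtraction()
        expected = truth["delta_m"].sum(axis=0) * ph.sensitivity
        assert np.allclose(perf, expected, atol=1e-10)

    def test_noise_level_matches_request(self):
        # The SNR parameter is defined on the tag/control perfusion image at
        # the shared volume budget (GM mean over background sd, sensitivity
        # bias excluded). The summed vessel-decoded image carries the known
        # factor-4 variance penalty, i.e. half the SNR.
        ph = make_phantom(shape=(32, 32, 8), seed=0)
        snr = 10.0
        timing = AcquisitionTiming(n_slices=8)
        gm_mean = None
        for scheme, expected in (("pcasl", snr), ("vepcasl", snr / 2.0)):
            series, truth = synthesize_series(ph, scheme, timing,
                                              snr=snr, seed=2)
            if scheme == "pcasl":
                perf_avg = series.pairwise_subtraction().mean(axis=0)
            else:
                dec = decode_matrix_inversion(series.averaged(),
                                              truth["encoding_matrix"])
                perf_avg = dec.total.mean(axis=0)
            bg_sd = float(perf_avg[ph.background_mask].std())
            gm_mean = float(truth["delta_m"].sum(0)[:, ph.gm_mask].mean())
            assert gm_mean / bg_sd == pytest.approx(expected, rel=0.15)

    def test_volume_budget_and_metadata(self, noiseless):
        _, series, _ = noiseless
        assert series.data.shape[0] == 96  # 2 repeats x 8 cycles x 6 PLDs
        assert len(series.cycle_names) == 8
        assert len(series.plds) == 6
        counts = np.bincount(series.cycle_ids)
        assert np.all(counts == 12)

    def test_bad_scheme_raises(self, small_phantom):
        with pytest.raises(ValueError):
            synthesize_series(small_phantom, "casl")


class TestIO:
    def test_series_round_trip(self, tmp_path, small_phantom):
        series, _ = synthesize_series(
            small_phantom, "pcasl", AcquisitionTiming(n_slices=8),
            snr=30.0, seed=1, n_volumes=24)
        series.save(tmp_path / "acq")
        back = PerfusionSeries.load(tmp_path / "acq")
        assert np.allclose(back.data, series.data, atol=1e-5)
        assert back.cycle_names == series.cycle_names
        assert np.array_equal(back.cycle_ids, series.cycle_ids)
        assert np.array_equal(back.pld_ids, series.pld_ids)
        assert np.allclose(back.affine, series.affine)

    def test_volume_round_trip(self, tmp_path):
        arr = np.arange(24.0).reshape(2, 3, 4)
        aff = np.diag([3.4, 3.4, 5.0, 1.0])
        save_volume(arr, aff, tmp_path / "v.nii")
        assert np.allclose(load_volume(tmp_path / "v.nii"), arr)
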