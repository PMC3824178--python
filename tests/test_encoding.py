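"""Encoding-matrix construction and the two decoders."""

import numpy as np
import pytest

from vepcasl import (EncodingCycle, decode_map, decode_matrix_inversion,
                     encoding_weight, geometry_encoding_matrix,
                     ideal_encoding_matrix, optimize_vessel_offset,
                     rectangular_geometry, standard_cycles)
from vepcasl.encoding import (decoded_component_covariance, map_classes,
                              _estimate_noise_variance)


def synth(a: np.ndarray, comps: np.ndarray, static: np.ndarray) -> np.ndarray:
    """Forward model: y_c = static + sum_j a_cj * DeltaM_j / 2."""
    return (np.einsum("cj,jpv->cpv", a[:, :-1], comps) / 2.0
            + a[:, -1][:, None, None] * static[None])


class TestMatrix:
    def test_ideal_matrix_invariants(self):
        a = ideal_encoding_matrix()
        assert a.shape == (8, 5)
        assert np.linalg.matrix_rank(a) == 5
        # orthogonal columns, each with norm^2 = number of cycles
        assert np.allclose(a.T @ a, 8 * np.eye(5))
        # every artery tagged four times and controlled four times
        assert np.all((a[:, :4] == -1).sum(axis=0) == 4)
        assert np.all((a[:, :4] == +1).sum(axis=0) == 4)

    def test_geometry_reproduces_ideal_matrix(self):
        geom = rectangular_geometry()
        a = geometry_encoding_matrix(standard_cycles(geom), geom)
        assert np.allclose(a, ideal_encoding_matrix(), atol=1e-12)

    def test_geometry_matrix_shifted_vessels_stays_full_rank(self):
        geom = rectangular_geometry().translated(3.0, -2.0)
        a = geometry_encoding_matrix(standard_cycles(geom), geom)
        assert np.linalg.matrix_rank(a) == 5

    def test_encoding_weight_extremes(self):
        cyc = EncodingCycle("selective", (1.0, 0.0), period=100.0,
                            tag_center=-25.0)
        assert encoding_weight((-25.0, 7.0), cyc) == pytest.approx(-1.0)
        assert encoding_weight((25.0, -3.0), cyc) == pytest.approx(+1.0)
        assert encoding_weight((0.0, 0.0), cyc) == pytest.approx(0.0)
        assert encoding_weight((1.0, 1.0), EncodingCycle("tag_all")) == -1.0
        assert encoding_weight((1.0, 1.0), EncodingCycle("control_all")) == 1.0

    def test_invalid_cycles_raise(self):
        with pytest.raises(ValueError):
            EncodingCycle("selective", period=0.0)
        with pytest.raises(ValueError):
            EncodingCycle("banana")
        with pytest.raises(ValueError):
            EncodingCycle("selective", direction=(0.0, 0.0), period=1.0)


class TestMatrixInversionDecode:
    def test_noiseless_round_trip(self, rng):
        a = ideal_encoding_matrix()
        comps = rng.gamma(2.0, 1.0, (4, 6, 10))
        static = rng.normal(50.0, 5.0, (6, 10))
        dec = decode_matrix_inversion(synth(a, comps, static), a)
        assert np.allclose(dec.components, comps, atol=1e-10)
        assert np.allclose(dec.static, static, atol=1e-10)
        assert np.allclose(dec.total, comps.sum(axis=0), atol=1e-9)

    def test_total_equals_pairwise_subtraction(self, rng):
        # summed decoded components on noiseless data = control - tag
        a = ideal_encoding_matrix()
        comps = rng.gamma(2.0, 1.0, (4, 6, 5))
        static = rng.normal(50.0, 5.0, (6, 5))
        y = synth(a, comps, static)
        dec = decode_matrix_inversion(y, a)
        assert np.allclose(dec.total, y[1] - y[0], atol=1e-9)

    def test_rank_deficient_matrix_raises(self):
        a = ideal_encoding_matrix()
        a[:, 1] = a[:, 0]
        with pytest.raises(np.linalg.LinAlgError):
            decode_matrix_inversion(np.zeros((8, 6, 3)), a)

    def test_raw_solution_covariance_analytic(self):
        cov = decoded_component_covariance(ideal_encoding_matrix(), sigma=2.0)
        assert np.allclose(cov, 4.0 / 8.0 * np.eye(5), atol=1e-12)

    def test_component_variance_monte_carlo(self):
        a = ideal_encoding_matrix()
        rng = np.random.default_rng(7)
        y = rng.normal(0.0, 1.0, (8, 1, 20000))
        dec = decode_matrix_inversion(y, a)
        var = dec.components[:, 0].var(axis=1).mean(axis=0)
        # components are 2x the raw solution: var = 4 * sigma^2 / 8
        assert var == pytest.approx(0.5, rel=0.05)


class TestNoiseEstimate:
    def test_unbiased_on_pure_noise(self):
        a = ideal_encoding_matrix()
        rng = np.random.default_rng(3)
        y = rng.normal(0.0, 1.5, (8, 6, 4000))
        var = _estimate_noise_variance(y, a)
        assert var.mean() == pytest.approx(1.5 ** 2, rel=0.02)

    def test_signal_does_not_leak_into_noise(self, rng):
        a = ideal_encoding_matrix()
        comps = rng.gamma(2.0, 1.0, (4, 6, 500))
        static = rng.normal(50.0, 5.0, (6, 500))
        y = synth(a, comps, static) + rng.normal(0.0, 0.3, (8, 6, 500))
        var = _estimate_noise_variance(y, a)
        assert var.mean() == pytest.approx(0.09, rel=0.15)


class TestMapDecode:
    def test_class_enumeration(self):
        cls = map_classes(4)
        assert cls[0] == ()
        assert len(cls) == 1 + 4 + 6
        assert (0, 1) in cls and (2, 3) in cls

    def test_classifies_singleton_pair_and_static(self):
        a = ideal_encoding_matrix()
        n_pld = 6
        comps = np.zeros((4, n_pld, 3))
        comps[0, :, 0] = 2.0                  # voxel 0: RICA only
        comps[1, :, 1] = 1.2                  # voxel 1: LICA + LVA
        comps[3, :, 1] = 0.8
        static = np.full((n_pld, 3), 30.0)    # voxel 2: static only
        rng = np.random.default_rng(11)
        y = synth(a, comps, static) + rng.normal(0.0, 0.02, (8, n_pld, 3))
        dec = decode_map(y, a, noise_var=0.02 ** 2)
        assert dec.classes[dec.class_label[0]] == (0,)
        assert dec.classes[dec.class_label[1]] == (1, 3)
        assert dec.classes[dec.class_label[2]] == ()
        # arteries outside the winning class are exactly zero
        assert np.all(dec.components[1:, :, 0] == 0.0)
        # per-PLD component sd is 2*sigma/sqrt(8) ~ 0.014; allow ~5 sd
        assert np.allclose(dec.components[0, :, 0], 2.0, atol=0.08)
        assert np.allclose(dec.components[1, :, 1], 1.2, atol=0.08)
        assert np.allclose(dec.components[3, :, 1], 0.8, atol=0.08)
        assert np.allclose(dec.static, 30.0, atol=0.08)

    def test_map_beats_matrix_inversion_on_single_artery_voxels(self):
        a = ideal_encoding_matrix()
        truth = np.zeros((4, 6, 400))
        truth[2] = 1.0                         # all voxels fed by RVA only
        static = np.full((6, 400), 20.0)
        rng = np.random.default_rng(5)
        y = synth(a, truth, static) + rng.normal(0.0, 0.25, (8, 6, 400))
        err_mi = np.abs(decode_matrix_inversion(y, a).components - truth).mean()
        err_map = np.abs(decode_map(y, a, noise_var=0.25 ** 2).components
                         - truth).mean()
        assert err_map < 0.6 * err_mi

    def test_estimated_noise_matches_known_noise_labels(self):
        a = ideal_encoding_matrix()
        truth = np.zeros((4, 6, 100))
        truth[1] = 1.5
        static = np.full((6, 100), 25.0)
        rng = np.random.default_rng(9)
        y = synth(a, truth, static) + rng.normal(0.0, 0.1, (8, 6, 100))
        dec_known = decode_map(y, a, noise_var=0.01)
        dec_est = decode_map(y, a)
        agree = np.mean(dec_known.class_label == dec_est.class_label)
        assert agree > 0.95


class TestOffsetSearch:
    def test_recovers_known_shift(self, rng):
        geom = rectangular_geometry()
        cycles = standard_cycles(geom)
        true_geom = geom.translated(3.0, -2.0)
        a_true = geometry_encoding_matrix(cycles, true_geom, cond_warn=np.inf)
        comps = np.zeros((4, 6, 120))
        for k in range(4):
            comps[k, :, k * 30:(k + 1) * 30] = 1.0
        static = np.full((6, 120), 20.0)
        y = synth(a_true, comps, static) + rng.normal(0, 0.05, (8, 6, 120))
        (dx, dy), a = optimize_vessel_offset(y, cycles, geom, max_shift=4.0,
                                             step=1.0, n_subsample=120)
        # with every vessel at a modulation extremum the matrix is exactly
        # even in the offset, so the shift is identified up to a global sign
        assert (dx, dy) in [(3.0, -2.0), (-3.0, 2.0)]
        assert np.allclose(a, a_true)

    def test_requires_selective_cycles(self):
        with pytest.raises(ValueError):
            optimize_vessel_offset(np.zeros((2, 6, 4)),
                                   [EncodingCycle("tag_all"),
                                    EncodingCycle("control_all")],
                                   rectangular_geometry())
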