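"""Comparison statistics between two CBF map sets.

Because both map sets carry substantial, spatially varying uncertainty, an
ordinary least-squares regression between them is biased. The slope and
intercept are instead found by minimizing an uncertainty-weighted chi-square

    chi2(m, c) = sum_i (f_b_i - m f_a_i - c)^2 / (sigma_b_i^2 + m^2 sigma_a_i^2)

whose numerator is the squared difference between the observed and expected
second-method CBF and whose denominator is the squared uncertainty of that
difference. Equivalent maps give m ~ 1, c ~ 0.

Also provided: exclusion of multi-supply voxels (significant perfusion from
two or more arteries with a large between-artery arrival-time difference,
which genuinely differ between the methods) and the SNR comparison with
dominant-artery territory masking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

log_inf = np.inf


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    chi2: float
    n_voxels: int


def _chi2(m: float, c: float, fa, sa, fb, sb) -> float:
    denom = sb ** 2 + m ** 2 * sa ** 2
    return float(np.sum((fb - m * fa - c) ** 2 / denom))


def chi2_regression(f_a, sigma_a, f_b, sigma_b) -> RegressionResult:
    """Uncertainty-weighted straight-line fit of map B against map A.

    The intercept is closed-form given the slope (a weighted mean), so the
    minimization is a one-dimensional search over the slope, started from the
    ordinary least-squares estimate.
    """
    fa, sa, fb, sb = (np.asarray(x, dtype=float).ravel()
                      for x in (f_a, sigma_a, f_b, sigma_b))
    if not (fa.size == sa.size == fb.size == sb.size):
        raise ValueError("inputs must have equal length")
    if fa.size <= 2:
        raise ValueError("need more than two voxels")
    if np.any(sa <= 0) or np.any(sb <= 0):
        raise ValueError("uncertainties must be positive")
    if np.ptp(fa) == 0:
        raise ValueError("degenerate regression: constant predictor")

    def c_of_m(m: float) -> float:
        w = 1.0 / (sb ** 2 + m ** 2 * sa ** 2)
        return float(np.sum(w * (fb - m * fa)) / np.sum(w))

    def objective(m: float) -> float:
        return _chi2(m, c_of_m(m), fa, sa, fb, sb)

    m_ols = float(np.polyfit(fa, fb, 1)[0])
    span = max(1.0, abs(m_ols))
    res = optimize.minimize_scalar(objective,
                                   bounds=(m_ols - 5 * span, m_ols + 5 * span),
                                   method="bounded",
                                   options={"xatol": 1e-12})
    m = float(res.x)
    c = c_of_m(m)
    return RegressionResult(m, c, _chi2(m, c, fa, sa, fb, sb), fa.size)


def chi2_regression_grid(f_a, sigma_a, f_b, sigma_b,
                         m_grid, c_grid) -> RegressionResult:
    """Brute-force 2D grid minimization of the same objective (slow oracle)."""
    fa, sa, fb, sb = (np.asarray(x, dtype=float).ravel()
                      for x in (f_a, sigma_a, f_b, sigma_b))
    best = (np.inf, np.nan, np.nan)
    for m in m_grid:
        for c in c_grid:
            v = _chi2(m, c, fa, sa, fb, sb)
            if v < best[0]:
                best = (v, m, c)
    return RegressionResult(float(best[1]), float(best[2]), float(best[0]),
                            fa.size)


def exclude_multi_supply(cbf: np.ndarray, cbf_var: np.ndarray,
                         bat: np.ndarray,
                         bat_diff_threshold: float = 0.5,
                         p_threshold: float = 0.01) -> np.ndarray:
    """Mask (True = keep) rejecting voxels with discordant multi-artery supply.

    A voxel is excluded when at least two arteries show perfusion
    significantly greater than zero (one-sided Gaussian test on the posterior
    mean/variance) and the arrival-time spread among those arteries exceeds
    ``bat_diff_threshold``. Inputs have a leading artery axis.
    """
    cbf = np.asarray(cbf, dtype=float)
    cbf_var = np.asarray(cbf_var, dtype=float)
    bat = np.asarray(bat, dtype=float)
    z_crit = stats.norm.isf(p_threshold)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = cbf / np.sqrt(cbf_var)
    signif = np.nan_to_num(z, nan=-np.inf) > z_crit
    n_signif = signif.sum(axis=0)
    bat_sig = np.where(signif, bat, np.nan)
    with np.errstate(all="ignore"):
        spread = np.nanmax(bat_sig, axis=0) - np.nanmin(bat_sig, axis=0)
    spread = np.nan_to_num(spread, nan=0.0)
    exclude = (n_signif >= 2) & (spread > bat_diff_threshold)
    return ~exclude


def territory_snr(perfusion_mean: np.ndarray, gm_mask: np.ndarray,
                  background_roi: np.ndarray,
                  decoded_mean: np.ndarray | None = None
                  ) -> dict[str, float]:
    """SNR of PLD-and-repeat-averaged perfusion images.

    ``perfusion_mean`` is the non-selective image (already averaged over
    repeats and PLDs); ``decoded_mean`` optionally adds per-artery averaged
    images with a leading artery axis. The per-artery signal mean is taken
    over GM voxels where that artery is the dominant supplier; the matched
    non-selective SNR uses the identical mask. Also reports the
    summed-components SNR over all GM.
    """
    gm = np.asarray(gm_mask, dtype=bool)
    bg = np.asarray(background_roi, dtype=bool)
    noise_sd = float(np.asarray(perfusion_mean)[bg].std())

    def snr(img, mask):
        if not mask.any():
            return np.nan
        s = float(np.asarray(img)[mask].mean())
        return np.inf if noise_sd == 0 else s / noise_sd

    out = {"PCASL_GM": snr(perfusion_mean, gm)}
    if decoded_mean is not None:
        dec = np.asarray(decoded_mean, dtype=float)
        dominant = np.argmax(dec, axis=0)
        for k in range(dec.shape[0]):
            mask = gm & (dominant == k)
            if not mask.any():
                continue
            out[f"VEPCASL_territory{k}"] = snr(dec[k], mask)
            out[f"PCASL_territory{k}"] = snr(perfusion_mean, mask)
        summed = dec.sum(axis=0)
        bg_sd_sum = float(summed[bg].std())
        s = float(summed[gm].mean())
        out["VEPCASL_summed_GM"] = np.inf if bg_sd_sum == 0 else s / bg_sd_sum
    return out
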