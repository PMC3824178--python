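"""Absolute calibration of perfusion maps.

Two steps convert fitted perfusion amplitudes into mL/100 g per minute:

1. Receive-coil sensitivity correction: the ratio of a head-coil to a
   body-coil calibration image (the body coil is assumed spatially uniform)
   estimates the receive sensitivity; dividing the perfusion and head-coil
   images by it removes the spatial bias.

2. CSF-referenced equilibrium magnetization: the mean signal in an eroded
   ventricle mask, corrected for the T1 and T2* of CSF at the calibration TR
   and TE, gives M0_CSF; correcting further for the blood/CSF relative proton
   density, the blood T2*, the density of brain tissue and the labeling
   inversion efficiency yields the effective blood magnetization M0_b that
   divides the perfusion signal.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .config import CalibrationConstants

log = logging.getLogger(__name__)


def coil_sensitivity_map(head_coil: np.ndarray, body_coil: np.ndarray,
                         smooth_sigma_vox: float = 1.0,
                         clamp: float = 1e-3,
                         mask: np.ndarray | None = None) -> np.ndarray:
    """Estimate the receive sensitivity as smoothed head/body image ratio.

    Zero (or near-zero) body-coil voxels inside the mask are infilled from the
    smoothed neighborhood before the division; the result is clamped away from
    zero so that correction by division is always defined.
    """
    head = np.asarray(head_coil, dtype=float)
    body = np.asarray(body_coil, dtype=float).copy()
    if head.shape != body.shape:
        raise ValueError("calibration volumes must share a grid")
    if mask is None:
        mask = body > 0
    bad = mask & (body <= 0)
    if np.any(bad):
        log.info("infilling %d zero body-coil voxels", int(bad.sum()))
        filled = ndimage.gaussian_filter(np.where(bad, 0.0, body), 2.0)
        norm = ndimage.gaussian_filter((~bad).astype(float), 2.0)
        body[bad] = (filled / np.maximum(norm, 1e-12))[bad]
    ratio = np.zeros_like(head)
    ok = body > 0
    ratio[ok] = head[ok] / body[ok]
    if smooth_sigma_vox > 0:
        w = ok.astype(float)
        ratio = ndimage.gaussian_filter(ratio * w, smooth_sigma_vox)
        norm = ndimage.gaussian_filter(w, smooth_sigma_vox)
        ratio = ratio / np.maximum(norm, 1e-12)
    return np.maximum(ratio, clamp)


def correct_sensitivity(image: np.ndarray, sensitivity: np.ndarray) -> np.ndarray:
    """Divide an image (perfusion or head-coil calibration) by the sensitivity."""
    return np.asarray(image, dtype=float) / sensitivity


def m0_blood_from_csf(calib_volume: np.ndarray, ventricle_mask: np.ndarray,
                      c: CalibrationConstants | None = None,
                      erode_iterations: int = 1) -> float:
    """Effective blood equilibrium magnetization from the CSF reference.

    M0_CSF = mean ventricular signal / [(1 - exp(-TR/T1_CSF)) exp(-TE/T2*_CSF)]
    M0_b   = M0_CSF * rho_rel * exp(-TE/T2*_b) * brain_density * alpha
    """
    c = c or CalibrationConstants()
    mask = np.asarray(ventricle_mask, dtype=bool)
    if erode_iterations > 0:
        eroded = ndimage.binary_erosion(mask, iterations=erode_iterations)
        if eroded.any():
            mask = eroded  # partial-volume guard; keep original if too small
        else:
            log.warning("ventricle mask vanished under erosion; using uneroded mask")
    if not mask.any():
        raise ValueError("empty ventricle mask: calibration failed")
    mean_csf = float(np.asarray(calib_volume, dtype=float)[mask].mean())
    recovery = (1.0 - np.exp(-c.tr_calib / c.t1_csf)) * np.exp(-c.te / c.t2s_csf)
    m0_csf = mean_csf / recovery
    return float(m0_csf * c.rel_proton_density_blood_csf
                 * np.exp(-c.te / c.t2s_blood)
                 * c.brain_density * c.inversion_efficiency)


def calibrate_cbf(fit_maps: dict[str, np.ndarray] | np.ndarray,
                  m0b: float) -> dict[str, np.ndarray] | np.ndarray:
    """Divide fitted amplitude maps by the effective M0_b.

    The kinetic model already carries the mL/100 g per minute unit rule, so
    fitted amplitudes are CBF-in-physical-units times M0_b; a single division
    completes the calibration. Vessel-decoded maps are calibrated per artery
    with the same M0_b. Accepts either a raw array or the map dict from
    ``fit_volume`` (only CBF-scaled entries are divided).
    """
    if m0b <= 0:
        raise ValueError("m0b must be positive")
    if isinstance(fit_maps, np.ndarray):
        return fit_maps / m0b
    out = {}
    for key, arr in fit_maps.items():
        if key in ("cbf", "total_cbf"):
            out[key] = arr / m0b
        elif key in ("cbf_var",):
            out[key] = arr / m0b ** 2
        else:
            out[key] = arr
    return out
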