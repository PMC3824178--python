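"""Digital head phantom and synthetic vessel-encoded acquisitions.

Everything the processing chain needs is generated here with no external
data: a four-territory head phantom (territory labels, tissue partial
volumes, per-artery perfusion and arrival-time fields, a smooth
coil-sensitivity bias and a ventricle mask), multi-PLD vessel-encoded or
tag/control time series with slice-timing offsets and background-suppressed
static tissue, and head/body-coil calibration volumes. All volumes can be
written to and read from NIfTI-1 with the correct voxel dimensions; the
per-volume cycle/PLD metadata travels in a JSON sidecar.

The phantom is deliberately schematic (ellipsoidal head, quadrant-like
territories) — it emulates the acquisition physics, not anatomy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from . import bloch
from .config import ARTERIES, BSUP_T1OPT_BY_PLD, AcquisitionTiming
from .encoding import (EncodingCycle, VesselGeometry, geometry_encoding_matrix,
                       rectangular_geometry, standard_cycles)
from .kinetic import casl_signal_arrays
from .two_artery import snr_to_noise_sigma


@dataclass
class Phantom:
    """Ground-truth digital head.

    ``territory_frac`` holds each artery's supply fraction per voxel
    (summing to 1 where perfused); ``cbf``/``bat`` are per-artery fields on
    the same leading axis. ``m0b`` is the true effective blood equilibrium
    magnetization that calibration should recover.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    territory_frac: np.ndarray          # (4, nx, ny, nz)
    cbf: np.ndarray                     # (4, nx, ny, nz), mL/100 g/min
    bat: np.ndarray                     # (4, nx, ny, nz), s
    abv: np.ndarray                     # (nx, ny, nz)
    pv_gm: np.ndarray
    pv_wm: np.ndarray
    pv_csf: np.ndarray
    t1_map: np.ndarray
    t2s_map: np.ndarray
    m0_map: np.ndarray                  # equilibrium tissue/CSF magnetization
    sensitivity: np.ndarray
    ventricle_mask: np.ndarray
    background_mask: np.ndarray
    brain_mask: np.ndarray
    m0b: float
    geometry: VesselGeometry = field(default_factory=rectangular_geometry)

    @property
    def affine(self) -> np.ndarray:
        return np.diag(list(self.voxel_size) + [1.0])

    @property
    def gm_mask(self) -> np.ndarray:
        return self.pv_gm > 0.5

    @property
    def total_cbf(self) -> np.ndarray:
        return self.cbf.sum(axis=0)


def make_phantom(shape: tuple[int, int, int] = (64, 64, 24),
                 voxel_size: tuple[float, float, float] = (3.4, 3.4, 5.0),
                 gm_cbf: float = 60.0,
                 wm_cbf: float = 20.0,
                 mixed_band_width: float = 12.0,
                 mixed_split: float = 0.5,
                 mixed_bat_offset: float = 0.4,
                 abv_peak: float = 0.0,
                 seed: int = 0) -> Phantom:
    """Build the deterministic (seeded) digital head phantom.

    Territories follow a nearest-artery partition of the axial plane
    (carotids anterior, vertebrals posterior); voxels within
    ``mixed_band_width`` mm of a territory boundary receive blood from the two
    adjacent arteries with the given split and an arrival-time offset on the
    later artery, emulating collateral-like mixed supply. BAT varies smoothly
    within each territory.
    """
    if not 0.0 < mixed_split < 1.0:
        raise ValueError("mixed_split must be in (0, 1)")
    rng = np.random.default_rng(seed)
    nx, ny, nz = shape
    dx, dy, dz = voxel_size
    x = (np.arange(nx) - (nx - 1) / 2) * dx
    y = (np.arange(ny) - (ny - 1) / 2) * dy
    z = (np.arange(nz) - (nz - 1) / 2) * dz
    xg, yg, zg = np.meshgrid(x, y, z, indexing="ij")

    rx, ry, rz = 0.42 * nx * dx, 0.45 * ny * dy, 0.55 * nz * dz
    head = (xg / rx) ** 2 + (yg / ry) ** 2 + (zg / rz) ** 2 <= 1.0
    brain = (xg / (0.88 * rx)) ** 2 + (yg / (0.88 * ry)) ** 2 \
        + (zg / (0.92 * rz)) ** 2 <= 1.0
    wm_core = (xg / (0.55 * rx)) ** 2 + (yg / (0.55 * ry)) ** 2 \
        + (zg / (0.7 * rz)) ** 2 <= 1.0
    ventricles = ((np.abs(xg) < 0.18 * rx) & (np.abs(yg - 0.05 * ry) < 0.22 * ry)
                  & (np.abs(zg) < 0.3 * rz) & brain)

    pv_csf = np.where(ventricles, 1.0, 0.0)
    pv_wm = np.where(wm_core & ~ventricles, 1.0, 0.0)
    pv_gm = np.where(brain & ~wm_core & ~ventricles, 1.0, 0.0)
    # soften tissue interfaces into partial volumes
    from scipy import ndimage
    k = 0.6
    pv_gm = ndimage.gaussian_filter(pv_gm, k)
    pv_wm = ndimage.gaussian_filter(pv_wm, k)
    pv_csf = ndimage.gaussian_filter(pv_csf, k)
    total = pv_gm + pv_wm + pv_csf
    scale = np.where(brain & (total > 1.0), total, 1.0)
    pv_gm, pv_wm, pv_csf = pv_gm / scale, pv_wm / scale, pv_csf / scale
    for pv in (pv_gm, pv_wm, pv_csf):
        pv[~brain] = 0.0

    # territories: nearest artery in the axial plane, with a seeded jitter of
    # the territory centers so different seeds move the boundaries
    centers = np.array([[-0.3, 0.35], [0.3, 0.35], [-0.3, -0.45], [0.3, -0.45]])
    centers = centers + rng.normal(0.0, 0.02, centers.shape)
    cx = centers[:, 0] * nx * dx
    cy = centers[:, 1] * ny * dy
    d = np.stack([np.sqrt((xg - cx[k]) ** 2 + (yg - cy[k]) ** 2)
                  for k in range(4)])
    order = np.argsort(d, axis=0)
    nearest, second = order[0], order[1]
    d_sorted = np.sort(d, axis=0)
    boundary_dist = d_sorted[1] - d_sorted[0]
    mixed = (boundary_dist < mixed_band_width) & brain & (mixed_band_width > 0)

    frac = np.zeros((4,) + shape)
    for k in range(4):
        frac[k][nearest == k] = 1.0
    if np.any(mixed):
        for k in range(4):
            own = mixed & (nearest == k)
            frac[k][own] = mixed_split
        for k in range(4):
            sec = mixed & (second == k)
            frac[k][sec] += 1.0 - mixed_split
    frac[:, ~brain] = 0.0

    perf_total = gm_cbf * pv_gm + wm_cbf * pv_wm
    cbf = frac * perf_total[None]

    # smooth within-territory BAT: grows with in-plane distance from the
    # territory center, ~0.9 s proximal to ~1.4 s distal
    bat = np.empty((4,) + shape)
    for k in range(4):
        bat[k] = 0.9 + 0.5 * np.clip(d[k] / max(d[k][brain].max(), 1e-9), 0, 1)
    if np.any(mixed):
        for k in range(4):
            bat[k][mixed & (second == k)] += mixed_bat_offset

    abv = np.zeros(shape)
    if abv_peak > 0:
        arterial = (boundary_dist > 2 * mixed_band_width) & brain & (pv_gm > 0.5)
        abv[arterial] = abv_peak

    t1_map = 1.3 * pv_gm + 1.0 * pv_wm + 4.3 * pv_csf
    t1_map[t1_map <= 0] = 1.3
    t2s_map = 0.045 * (pv_gm + pv_wm) + 0.750 * pv_csf
    t2s_map[t2s_map <= 0] = 0.045
    m0_map = np.where(head, 0.75 * pv_gm + 0.65 * pv_wm + 1.0 * pv_csf, 0.0)
    m0_map[head & (m0_map == 0)] = 0.7  # scalp/skull filler

    # smooth receive-coil bias: quadratic falloff plus a mild lateral tilt
    r2 = (xg / (nx * dx)) ** 2 + (yg / (ny * dy)) ** 2 + (zg / (nz * dz)) ** 2
    sensitivity = 1.0 + 0.4 * np.exp(-4.0 * r2) + 0.1 * xg / (nx * dx)

    te, t2sb = 0.014, 0.050
    m0_csf = 1.0
    m0b = m0_csf * 0.87 * np.exp(-te / t2sb) * 1.05 * 0.88

    return Phantom(shape=shape, voxel_size=voxel_size, territory_frac=frac,
                   cbf=cbf, bat=bat, abv=abv, pv_gm=pv_gm, pv_wm=pv_wm,
                   pv_csf=pv_csf, t1_map=t1_map, t2s_map=t2s_map,
                   m0_map=m0_map, sensitivity=sensitivity,
                   ventricle_mask=ventricles, background_mask=~head,
                   brain_mask=brain, m0b=float(m0b))


@dataclass
class PerfusionSeries:
    """4D acquisition with per-volume cycle and PLD metadata."""

    data: np.ndarray                    # (n_volumes, nx, ny, nz)
    cycle_ids: np.ndarray               # (n_volumes,) index into cycle_names
    pld_ids: np.ndarray                 # (n_volumes,) index into plds
    cycle_names: tuple[str, ...]
    plds: tuple[float, ...]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def averaged(self) -> np.ndarray:
        """Average repeats -> (n_cycles, n_pld, nx, ny, nz)."""
        n_cyc, n_pld = len(self.cycle_names), len(self.plds)
        out = np.zeros((n_cyc, n_pld) + self.data.shape[1:])
        count = np.zeros((n_cyc, n_pld))
        for v in range(self.data.shape[0]):
            out[self.cycle_ids[v], self.pld_ids[v]] += self.data[v]
            count[self.cycle_ids[v], self.pld_ids[v]] += 1
        if np.any(count == 0):
            raise ValueError("missing cycle/PLD combinations")
        return out / count[:, :, None, None, None]

    def pairwise_subtraction(self) -> np.ndarray:
        """Control-minus-tag perfusion image per PLD (non-selective data)."""
        avg = self.averaged()
        names = self.cycle_names
        return avg[names.index("control_all")] - avg[names.index("tag_all")]

    def save(self, stem: str | Path) -> None:
        stem = Path(stem)
        img = nib.Nifti1Image(np.moveaxis(self.data, 0, -1).astype(np.float32),
                              self.affine)
        nib.save(img, str(stem) + ".nii")
        meta = {str(v): {"cycle": self.cycle_names[self.cycle_ids[v]],
                         "pld_s": self.plds[self.pld_ids[v]]}
                for v in range(self.data.shape[0])}
        sidecar = {"cycle_names": list(self.cycle_names),
                   "plds": list(self.plds), "volumes": meta}
        Path(str(stem) + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, stem: str | Path) -> "PerfusionSeries":
        stem = Path(stem)
        img = nib.load(str(stem) + ".nii")
        data = np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0)
        sidecar = json.loads(Path(str(stem) + ".json").read_text())
        names = tuple(sidecar["cycle_names"])
        plds = tuple(sidecar["plds"])
        cyc = np.array([names.index(sidecar["volumes"][str(v)]["cycle"])
                        for v in range(data.shape[0])])
        pld = np.array([plds.index(sidecar["volumes"][str(v)]["pld_s"])
                        for v in range(data.shape[0])])
        return cls(data, cyc, pld, names, plds, img.affine)


def _static_mz_by_slice(timing: AcquisitionTiming) -> np.ndarray:
    """Residual static-tissue Mz multiplier per (pld, slice, T1-of-voxel).

    Returns a callable-free lookup: for each PLD the solved two-inversion
    timing; evaluation happens in :func:`synthesize_series` voxelwise.
    """
    timings = []
    for pld in timing.plds:
        t1opt = BSUP_T1OPT_BY_PLD.get(round(float(pld), 3))
        if t1opt is None:
            t1opt = bloch.max_t1opt(float(pld), timing.tau)
        timings.append(bloch.solve_bsup_timings(t1opt, timing.tau, float(pld)))
    return timings


def synthesize_series(phantom: Phantom,
                      scheme: str = "vepcasl",
                      timing: AcquisitionTiming | None = None,
                      snr: float = 30.0,
                      seed: int = 0,
                      n_volumes: int = 96,
                      vessel_offset: tuple[float, float] = (0.0, 0.0),
                      ) -> tuple[PerfusionSeries, dict]:
    """Simulate the 4D acquisition.

    ``scheme`` is 'vepcasl' (8 encoding cycles) or 'pcasl' (tag/control
    pair); the fixed volume budget is shared, so the 2-cycle scheme gets more
    averages per PLD. Per-voxel signals sum the background-suppressed static
    tissue, each artery's kinetic component weighted by its encoding weight,
    and the macrovascular term; everything is multiplied by the coil
    sensitivity before Gaussian noise is added at the level implied by the
    requested image-domain SNR. ``vessel_offset`` shifts the true vessel
    positions (emulating motion after planning) without telling the decoder.

    Returns the series plus a ground-truth sidecar dict.
    """
    timing = timing or AcquisitionTiming(n_slices=phantom.shape[2])
    rng = np.random.default_rng(seed)
    geom = phantom.geometry.translated(*vessel_offset)
    if scheme == "vepcasl":
        cycles = standard_cycles(geom)
    elif scheme == "pcasl":
        cycles = [EncodingCycle("tag_all", name="tag_all"),
                  EncodingCycle("control_all", name="control_all")]
    else:
        raise ValueError("scheme must be 'vepcasl' or 'pcasl'")
    a = geometry_encoding_matrix(cycles, geom, cond_warn=np.inf)
    n_cyc = len(cycles)
    n_pld = len(timing.plds)
    reps = max(1, n_volumes // (n_cyc * n_pld))

    nz = phantom.shape[2]
    z_idx = np.arange(nz)

    # per-artery Delta-M fields: (4, n_pld, nx, ny, nz)
    dm = np.zeros((4, n_pld) + phantom.shape)
    for p_i, pld in enumerate(timing.plds):
        t_slice = timing.tau + pld + z_idx * timing.time_per_slice
        t_vox = np.broadcast_to(t_slice, phantom.shape)
        for k in range(4):
            dm[k, p_i] = casl_signal_arrays(t_vox, phantom.cbf[k],
                                            phantom.bat[k], timing.tau,
                                            m0b=phantom.m0b)
        if np.any(phantom.abv > 0):
            ta = np.clip(phantom.bat.min(axis=0) - 0.3, 0.0, None)
            box = (t_vox >= ta) & (t_vox < ta + timing.tau)
            mv = np.where(box, 2.0 * phantom.m0b * phantom.abv
                          * np.exp(-t_vox / 1.6), 0.0)
            # macrovascular blood is attributed to the locally dominant artery
            kdom = np.argmax(phantom.territory_frac, axis=0)
            for k in range(4):
                dm[k, p_i] += np.where(kdom == k, mv, 0.0)

    # static background-suppressed tissue per PLD and slice
    bsup_timings = _static_mz_by_slice(timing)
    static = np.zeros((n_pld,) + phantom.shape)
    for p_i, bt in enumerate(bsup_timings):
        for zi in range(nz):
            mz = bloch.bsup_mz(phantom.t1_map[:, :, zi].clip(1e-2),
                               bt, bt.readout_time + zi * timing.time_per_slice)
            static[p_i, :, :, zi] = mz * phantom.m0_map[:, :, zi]
    static[:, phantom.background_mask] = 0.0

    # noise level from the SNR definition (perfusion image averaged over all
    # repeats and PLDs; per-PLD perfusion noise var is sigma_vol^2/4 for both
    # schemes at the 96-volume budget, so PLD-averaging gives /24)
    gm = phantom.gm_mask
    ref = float(dm.sum(axis=0)[:, gm].mean())  # PLD-and-GM mean total Delta-M
    # per-PLD perfusion variance is 4 sigma_vol^2 / (volumes per PLD) for
    # both schemes, so the fully averaged perfusion image sees
    # sigma_vol^2 * 4 / n_volumes: the effective number of averages is
    # n_volumes / 4
    n_avg_equiv = reps * n_cyc * n_pld / 4.0
    sigma_vol = snr_to_noise_sigma(snr, ref, n_averages=n_avg_equiv) \
        if np.isfinite(snr) else 0.0

    vols = np.empty((reps * n_cyc * n_pld,) + phantom.shape)
    cyc_ids = np.empty(vols.shape[0], dtype=int)
    pld_ids = np.empty(vols.shape[0], dtype=int)
    v = 0
    for _ in range(reps):
        for p_i in range(n_pld):
            for c_i in range(n_cyc):
                clean = static[p_i].copy()
                for k in range(4):
                    clean += a[c_i, k] * 0.5 * dm[k, p_i]
                clean *= phantom.sensitivity
                if sigma_vol > 0:
                    clean = clean + rng.normal(0.0, sigma_vol, phantom.shape)
                vols[v] = clean
                cyc_ids[v] = c_i
                pld_ids[v] = p_i
                v += 1

    series = PerfusionSeries(vols, cyc_ids, pld_ids,
                             tuple(c.name for c in cycles),
                             tuple(float(p) for p in timing.plds),
                             affine=np.diag(list(phantom.voxel_size) + [1.0]))
    truth = {"cbf": phantom.cbf, "bat": phantom.bat,
             "total_cbf": phantom.total_cbf, "m0b": phantom.m0b,
             "encoding_matrix": a, "sigma_vol": sigma_vol,
             "delta_m": dm, "static": static}
    return series, truth


def synthesize_calibration(phantom: Phantom,
                           tr: float = 6.0, te: float = 0.014,
                           n_repeats: int = 3,
                           noise_sd_frac: float = 0.002,
                           seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Head-coil and body-coil calibration volumes (n_repeats each).

    Body-coil reception is assumed uniform; the head-coil image is the same
    object multiplied by the receive sensitivity. Signal follows saturation
    recovery at the calibration TR with T2* decay at the TE.
    """
    rng = np.random.default_rng(seed)
    sig = phantom.m0_map * (1.0 - np.exp(-tr / phantom.t1_map)) \
        * np.exp(-te / phantom.t2s_map)
    sig[phantom.background_mask] = 0.0
    body = np.stack([sig + rng.normal(0, noise_sd_frac * sig.max(), sig.shape)
                     for _ in range(n_repeats)])
    headc = np.stack([sig * phantom.sensitivity
                      + rng.normal(0, noise_sd_frac * sig.max(), sig.shape)
                      for _ in range(n_repeats)])
    return headc, body


def save_volume(arr: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine),
             str(path))


def load_volume(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)
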