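"""Vessel encoding and decoding.

Vessel-encoded PCASL acquires cycles in which the labeling efficiency is
modulated sinusoidally across the labeling plane, so each artery is either
tagged (-1), controlled (+1) or somewhere in between. A set of cycles forms an
encoding matrix A mapping the unknown per-artery signals plus a static term to
the measured volumes, y = A x. The canonical 8-cycle scheme for the four
brain-feeding arteries (RICA, LICA, RVA, LVA in a rectangular arrangement)
tags and controls every artery exactly four times; its matrix is full rank
with mutually orthogonal columns, so its decoding SNR matches a standard
tag/control PCASL acquisition of equal duration.

Sign convention: tag = -1, control = +1; the decoded artery components are
reported on the control-minus-tag perfusion-difference scale (Delta M), i.e.
twice the raw least-squares amplitude of the [-1, +1] model, so perfused
voxels give positive components and summing all arteries reproduces the
non-selective perfusion signal.

Two decoders are provided: plain pseudo-inverse (``decode_matrix_inversion``)
and a Bayesian maximum a posteriori classifier (``decode_map``) that assigns
every voxel to at most two feeding arteries and re-estimates the amplitudes
within that class, which suppresses noise from arteries that do not supply the
voxel.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import ARTERIES

log = logging.getLogger(__name__)


@dataclass
class VesselGeometry:
    """Ordered (name, x, y) positions of the arteries in the labeling plane (mm)."""

    vessels: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        names = [v[0] for v in self.vessels]
        if len(set(names)) != len(names) or not names:
            raise ValueError("vessel names must be unique and non-empty")

    @property
    def names(self) -> list[str]:
        return [v[0] for v in self.vessels]

    @property
    def positions(self) -> np.ndarray:
        return np.array([[v[1], v[2]] for v in self.vessels], dtype=float)

    def translated(self, dx: float, dy: float) -> "VesselGeometry":
        return VesselGeometry(tuple((n, x + dx, y + dy) for n, x, y in self.vessels))


def rectangular_geometry(half_width: float = 25.0,
                         carotid_y: float = 20.0,
                         vertebral_y: float = -20.0,
                         vertebral_half_width: float = 25.0) -> VesselGeometry:
    """Idealized rectangular arrangement: carotids anterior, vertebrals posterior."""
    return VesselGeometry((
        ("RICA", -half_width, carotid_y),
        ("LICA", +half_width, carotid_y),
        ("RVA", -vertebral_half_width, vertebral_y),
        ("LVA", +vertebral_half_width, vertebral_y),
    ))


@dataclass
class EncodingCycle:
    """One acquisition cycle.

    kind: 'tag_all', 'control_all' or 'selective'. Selective cycles modulate
    the labeling efficiency as -cos(2 pi (u - tag_center) / period) along the
    projection u of the vessel position onto ``direction``.
    """

    kind: str
    direction: tuple[float, float] = (1.0, 0.0)
    period: float = 0.0
    tag_center: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("tag_all", "control_all", "selective"):
            raise ValueError(f"unknown cycle kind {self.kind!r}")
        if self.kind == "selective" and self.period <= 0:
            raise ValueError("selective cycles need a positive period")
        if self.kind == "selective":
            d = np.asarray(self.direction, dtype=float)
            n = np.linalg.norm(d)
            if n == 0:
                raise ValueError("direction must be non-zero")
            self.direction = tuple(d / n)


def encoding_weight(position: Sequence[float], cycle: EncodingCycle) -> float:
    """Labeling weight in [-1, +1] of a vessel at ``position`` for one cycle."""
    if cycle.kind == "tag_all":
        return -1.0
    if cycle.kind == "control_all":
        return +1.0
    u = float(np.dot(position, cycle.direction))
    w = -np.cos(2.0 * np.pi * (u - cycle.tag_center) / cycle.period)
    return float(np.clip(w, -1.0, 1.0))


def standard_cycles(geom: VesselGeometry) -> list[EncodingCycle]:
    """The 8-cycle scheme: non-selective pair, left-right, anterior-posterior
    and diagonal encoding pairs, built from the vessel geometry.

    The diagonal pair exploits the periodicity of the encoding: the period is
    chosen so that tagging RICA and LVA simultaneously controls LICA and RVA.
    """
    pos = {n: p for n, p in zip(geom.names, geom.positions)}
    rica, lica = pos["RICA"], pos["LICA"]
    rva, lva = pos["RVA"], pos["LVA"]

    def pair(u_tag: float, u_ctl: float, direction, name_tag, name_ctl):
        d = np.asarray(direction, float)
        d = d / np.linalg.norm(d)
        period = 2.0 * abs(u_ctl - u_tag)
        return [
            EncodingCycle("selective", tuple(d), period, u_tag, name=name_tag),
            EncodingCycle("selective", tuple(d), period, u_ctl, name=name_ctl),
        ]

    cycles = [EncodingCycle("tag_all", name="tag_all"),
              EncodingCycle("control_all", name="control_all")]
    # left-right: right arteries vs left arteries along x
    ex = (1.0, 0.0)
    u_r = 0.5 * (rica[0] + rva[0])
    u_l = 0.5 * (lica[0] + lva[0])
    cycles += pair(u_r, u_l, ex, "tag_right", "tag_left")
    # anterior-posterior: carotids vs vertebrals along y
    ey = (0.0, 1.0)
    u_a = 0.5 * (rica[1] + lica[1])
    u_p = 0.5 * (rva[1] + lva[1])
    cycles += pair(u_a, u_p, ey, "tag_anterior", "tag_posterior")
    # diagonal: RICA+LVA vs LICA+RVA. The midpoints of the two diagonal pairs
    # coincide for a rectangle, so a half-period offset cannot separate them
    # directly; instead the periodicity of the encoding is exploited. Fit the
    # rectangle half-width a (left-right) and half-height b (anterior-
    # posterior): along the direction at angle atan(a / 3b) from x with period
    # P = 4 a cos(theta) / 3, RICA and LVA project one full period apart
    # (both tagged) while LICA and RVA land half a period away (controlled).
    center = 0.25 * (rica + lica + rva + lva)
    a_half = 0.25 * float(lica[0] + lva[0] - rica[0] - rva[0])
    b_half = 0.25 * float(rica[1] + lica[1] - rva[1] - lva[1])
    if abs(a_half) < 1e-9 or abs(b_half) < 1e-9:
        raise ValueError("degenerate vessel geometry: arteries are collinear")
    theta = np.arctan2(a_half, 3.0 * b_half)
    d = (float(np.cos(theta)), float(np.sin(theta)))
    period = 4.0 * a_half * np.cos(theta) / 3.0
    u_rica = float((np.array(rica) - center) @ d + center @ d)
    u_lica = float((np.array(lica) - center) @ d + center @ d)
    cycles.append(EncodingCycle("selective", d, abs(period), u_rica,
                                name="tag_rica_lva"))
    cycles.append(EncodingCycle("selective", d, abs(period), u_lica,
                                name="tag_lica_rva"))
    return cycles


def ideal_encoding_matrix() -> np.ndarray:
    """The 8x5 encoding matrix of the rectangular four-artery scheme.

    Columns: RICA, LICA, RVA, LVA, static. Rows: tag-all, control-all,
    tag-right, tag-left, tag-anterior, tag-posterior, tag RICA+LVA,
    tag LICA+RVA. Every artery is tagged and controlled four times each;
    all five columns are mutually orthogonal.
    """
    return np.array([
        [-1, -1, -1, -1, +1],
        [+1, +1, +1, +1, +1],
        [-1, +1, -1, +1, +1],
        [+1, -1, +1, -1, +1],
        [-1, -1, +1, +1, +1],
        [+1, +1, -1, -1, +1],
        [-1, +1, +1, -1, +1],
        [+1, -1, -1, +1, +1],
    ], dtype=float)


def geometry_encoding_matrix(cycles: Sequence[EncodingCycle],
                             geom: VesselGeometry,
                             cond_warn: float = 50.0) -> np.ndarray:
    """Assemble the encoding matrix for arbitrary vessel positions.

    Entry (i, j) is the labeling weight of vessel j under cycle i; the last
    column (static tissue) is +1 everywhere. Logs a warning when the matrix is
    poorly conditioned for decoding.
    """
    pos = geom.positions
    a = np.empty((len(cycles), len(pos) + 1))
    for i, cyc in enumerate(cycles):
        for j in range(len(pos)):
            a[i, j] = encoding_weight(pos[j], cyc)
    a[:, -1] = 1.0
    c = np.linalg.cond(a)
    if c > cond_warn:
        log.warning("encoding matrix poorly conditioned (cond=%.1f)", c)
    return a


@dataclass
class DecodedComponents:
    """Per-voxel, per-PLD artery signal estimates plus the static term.

    ``components`` has shape (n_vessels, n_pld) + spatial, on the
    control-minus-tag Delta-M scale; ``static`` has shape (n_pld,) + spatial.
    MAP decoding additionally fills ``class_label`` (index into ``classes``)
    and ``log_evidence``.
    """

    components: np.ndarray
    static: np.ndarray
    vessel_names: tuple[str, ...] = ARTERIES
    class_label: np.ndarray | None = None
    classes: list[tuple[int, ...]] | None = None
    log_evidence: np.ndarray | None = None

    @property
    def total(self) -> np.ndarray:
        """Summed-over-arteries (non-selective equivalent) perfusion signal."""
        return self.components.sum(axis=0)


def _as_voxel_matrix(data: np.ndarray) -> tuple[np.ndarray, tuple[int, ...]]:
    """Reshape (n_cycles, n_pld, *spatial) -> (n_cycles, n_pld, n_vox)."""
    spatial = data.shape[2:]
    return data.reshape(data.shape[0], data.shape[1], -1), spatial


def decode_matrix_inversion(data: np.ndarray, a: np.ndarray,
                            vessel_names: Sequence[str] = ARTERIES,
                            ) -> DecodedComponents:
    """Least-squares decoding of cycle-averaged data.

    ``data`` is (n_cycles, n_pld, *spatial). The raw solution of y = A x is
    scaled by 2 for the artery columns to express components on the
    control-minus-tag difference scale (the static column is left unscaled).
    """
    if np.linalg.matrix_rank(a) < a.shape[1]:
        raise np.linalg.LinAlgError("encoding matrix is rank deficient")
    y, spatial = _as_voxel_matrix(np.asarray(data, dtype=float))
    n_cyc, n_pld, n_vox = y.shape
    pinv = np.linalg.pinv(a)
    x = np.einsum("kc,cpv->kpv", pinv, y)
    comps = 2.0 * x[:-1]
    static = x[-1]
    return DecodedComponents(
        components=comps.reshape((a.shape[1] - 1, n_pld) + spatial),
        static=static.reshape((n_pld,) + spatial),
        vessel_names=tuple(vessel_names),
    )


def decoded_component_covariance(a: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Covariance of the raw least-squares solution under i.i.d. noise.

    For the ideal 8-cycle matrix this is sigma^2/8 on the diagonal with zero
    off-diagonal terms, the analytic statement of SNR parity with a matched
    tag/control PCASL acquisition.
    """
    pinv = np.linalg.pinv(a)
    return sigma ** 2 * pinv @ pinv.T


def map_classes(n_vessels: int) -> list[tuple[int, ...]]:
    """Candidate source classes: static-only, each single artery, each pair."""
    classes: list[tuple[int, ...]] = [()]
    classes += [(j,) for j in range(n_vessels)]
    classes += [c for c in itertools.combinations(range(n_vessels), 2)]
    return classes


def _estimate_noise_variance(y: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Per-voxel noise variance from full-rank least-squares residuals.

    y: (n_cycles, n_pld, n_vox). Residual degrees of freedom pool across PLDs.
    """
    n_cyc, n_pld, n_vox = y.shape
    pinv = np.linalg.pinv(a)
    resid = y - np.einsum("ck,kpv->cpv", a, np.einsum("kc,cpv->kpv", pinv, y))
    dof = (n_cyc - a.shape[1]) * n_pld
    if dof <= 0:
        raise ValueError("encoding scheme leaves no residual degrees of freedom")
    var = (resid ** 2).sum(axis=(0, 1)) / dof
    return np.maximum(var, 1e-30)


def decode_map(data: np.ndarray, a: np.ndarray,
               vessel_names: Sequence[str] = ARTERIES,
               signal_prior_sd: float = 10.0,
               static_prior_sd: float = 100.0,
               noise_var: np.ndarray | float | None = None,
               ) -> DecodedComponents:
    """Bayesian MAP decoding with class-based source selection.

    Every voxel is assumed to be fed by at most two arteries ("two vessels
    per class"). For each candidate class (static only, one artery, or an
    unordered pair of arteries, always plus static tissue) the linear
    sub-model with zero-mean Gaussian amplitude priors has a closed-form
    marginal likelihood; it is evaluated jointly across all PLDs and the
    class with the highest evidence is selected under a uniform class prior.
    Per-PLD amplitudes are then re-estimated as the posterior mean within the
    winning class; arteries outside the class are set exactly to zero.
    Relative prior scales are expressed in the data's signal units.
    """
    y, spatial = _as_voxel_matrix(np.asarray(data, dtype=float))
    n_cyc, n_pld, n_vox = y.shape
    n_ves = a.shape[1] - 1
    if noise_var is None:
        noise_var = _estimate_noise_variance(y, a)
    noise_var = np.broadcast_to(np.asarray(noise_var, dtype=float), (n_vox,))

    classes = map_classes(n_ves)
    # scale priors to the data so the evidence is unit-insensitive
    scale = max(float(np.sqrt(np.mean(y ** 2))), 1e-12)
    sd_sig = signal_prior_sd * scale
    sd_stat = static_prior_sd * scale

    yy = np.einsum("cpv,cpv->v", y, y)  # sum over cycles and PLDs of y^2
    sig2 = noise_var  # (n_vox,)

    log_ev = np.full((len(classes), n_vox), -np.inf)
    post_ops = []  # per class: (columns, posterior-mean amplitudes)
    for ci, cls in enumerate(classes):
        cols = list(cls) + [n_ves]
        ac = a[:, cols]
        s0h = np.array([sd_sig] * len(cls) + [sd_stat])  # prior sd per column
        # The per-PLD marginal covariance is C = A S0 A^T + sig2 I. With
        # B = S0^1/2 A^T A S0^1/2 = Q diag(lam) Q^T and z = Q^T S0^1/2 A^T y:
        #   y^T C^-1 y   = (y^T y - sum_i z_i^2/(lam_i+sig2)) / sig2
        #   log det C    = sum_i log(lam_i+sig2) + (n_cyc - k) log sig2
        #   E[theta | y] = S0^1/2 Q diag(1/(lam_i+sig2)) z
        b = (ac * s0h).T @ (ac * s0h)
        lam, q = np.linalg.eigh(b)
        lam = np.clip(lam, 0.0, None)
        aty = np.einsum("ck,cpv->kpv", ac, y)
        z = np.einsum("kj,kpv->jpv", q, aty * s0h[:, None, None])
        denom = lam[:, None] + sig2[None, :]  # (k, n_vox)
        z2 = (z ** 2).sum(axis=1)             # summed over PLDs
        quad = (yy - (z2 / denom).sum(axis=0)) / sig2
        logdet = np.log(denom).sum(axis=0) + (n_cyc - len(cols)) * np.log(sig2)
        log_ev[ci] = -0.5 * (quad + n_pld * logdet
                             + n_pld * n_cyc * np.log(2.0 * np.pi))
        xsol = np.einsum("kj,jpv->kpv", q, z / denom[:, None, :]) * s0h[:, None, None]
        post_ops.append((cols, xsol))

    best = np.argmax(log_ev, axis=0)
    comps = np.zeros((n_ves, n_pld, n_vox))
    static = np.zeros((n_pld, n_vox))
    for ci, (cols, xsol) in enumerate(post_ops):
        sel = best == ci
        if not np.any(sel):
            continue
        for k, col in enumerate(cols):
            if col == n_ves:
                static[:, sel] = xsol[k][:, sel]
            else:
                comps[col, :, sel] = 2.0 * xsol[k][:, sel].T
    return DecodedComponents(
        components=comps.reshape((n_ves, n_pld) + spatial),
        static=static.reshape((n_pld,) + spatial),
        vessel_names=tuple(vessel_names),
        class_label=best.reshape(spatial),
        classes=classes,
        log_evidence=log_ev.max(axis=0).reshape(spatial),
    )


def optimize_vessel_offset(data: np.ndarray,
                           cycles: Sequence[EncodingCycle],
                           geom: VesselGeometry,
                           max_shift: float = 10.0,
                           step: float = 1.0,
                           n_subsample: int = 256,
                           seed: int = 0,
                           ) -> tuple[tuple[float, float], np.ndarray]:
    """Grid-search a global in-plane translation of the vessel positions.

    Accounts for rigid subject motion between vessel planning and the ASL
    acquisition by maximizing the summed MAP log-evidence over a voxel
    subsample. Returns the best (dx, dy) in mm and the corrected encoding
    matrix.
    """
    if not any(c.kind == "selective" for c in cycles):
        raise ValueError("offset search requires selective cycles")
    y, spatial = _as_voxel_matrix(np.asarray(data, dtype=float))
    n_vox = y.shape[2]
    rng = np.random.default_rng(seed)
    # prefer voxels with perfusion signal: rank by tag/control difference
    diff = np.abs(y[1] - y[0]).mean(axis=0)
    order = np.argsort(diff)[::-1]
    idx = order[:min(n_subsample, n_vox)]
    ysub = y[:, :, idx]
    if float(diff[idx].max(initial=0.0)) <= 0:
        log.warning("no perfusion signal found; returning zero offset")
        return (0.0, 0.0), geometry_encoding_matrix(cycles, geom)

    shifts = np.arange(-max_shift, max_shift + step / 2, step)
    best = (-np.inf, (0.0, 0.0), None)
    for dx in shifts:
        for dy in shifts:
            a = geometry_encoding_matrix(cycles, geom.translated(dx, dy),
                                         cond_warn=np.inf)
            if np.linalg.matrix_rank(a) < a.shape[1]:
                continue
            dec = decode_map(ysub.reshape(ysub.shape[0], ysub.shape[1], -1), a)
            score = float(dec.log_evidence.sum())
            if score > best[0] or (score == best[0] and (dx, dy) == (0.0, 0.0)):
                best = (score, (float(dx), float(dy)), a)
    _, offset, a = best
    if a is None:
        log.warning("offset search failed; returning zero offset")
        return (0.0, 0.0), geometry_encoding_matrix(cycles, geom)
    return offset, a
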