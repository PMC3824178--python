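"""Closed-form ASL signal models for continuous labeling.

The tissue component follows the single-compartment general kinetic model for
a continuous-labeling bolus of duration ``tau``: no signal before the bolus
arrival time ``bat``, an inflow phase while the bolus is being delivered, and
clearance afterwards governed by the tissue relaxation time. The macrovascular
component describes labeled blood still inside large vessels: a boxcar of
width ``tau`` starting at the arterial arrival time, decaying with the blood
T1.

Signals are expressed on the control-minus-tag difference scale (Delta M).
Perfusion ``cbf`` is given in mL/100 g per minute and converted internally to
s^-1 by dividing by 6000 (100 g per mL-equivalent x 60 s/min). The brain/blood
partition coefficient is deliberately not folded in here: calibration divides
by an effective *blood* equilibrium magnetization, so the model carries
``m0b`` directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import AcquisitionTiming

#: conversion from mL/100 g per minute to s^-1
CBF_UNIT_SCALE = 6000.0


@dataclass
class KineticParams:
    """Parameters of one arterial component feeding a voxel.

    cbf: perfusion rate (mL/100 g per minute); bat: bolus arrival time (s);
    abv: arterial blood volume fraction of the macrovascular term;
    bat_art: macrovascular arrival time (s), typically slightly earlier
    than the tissue bolus arrival.
    """

    cbf: float
    bat: float
    t1_blood: float = 1.6
    t1_tissue: float = 1.3
    m0b: float = 1.0
    abv: float = 0.0
    bat_art: float | None = None

    def __post_init__(self) -> None:
        if self.cbf < 0:
            raise ValueError("cbf must be non-negative")
        if self.bat <= 0:
            raise ValueError("bat must be positive")
        if self.t1_blood <= 0 or self.t1_tissue <= 0:
            raise ValueError("relaxation times must be positive")
        if self.abv < 0:
            raise ValueError("abv must be non-negative")
        if self.bat_art is None:
            # macrovascular blood precedes tissue delivery
            self.bat_art = max(0.0, self.bat - 0.3)


def casl_signal_arrays(t, cbf, bat, tau: float, t1_blood=1.6, t1_tissue=1.3,
                       m0b=1.0) -> np.ndarray:
    """Vectorized tissue Delta-M; all arguments broadcast against each other.

    Used directly by the phantom generator where perfusion and arrival time
    vary voxelwise; :func:`casl_tissue_signal` is the scalar-parameter view.
    """
    t, cbf, bat = np.broadcast_arrays(np.asarray(t, float),
                                      np.asarray(cbf, float),
                                      np.asarray(bat, float))
    f = cbf / CBF_UNIT_SCALE
    t1p = t1_tissue
    pref = 2.0 * m0b * f * t1p * np.exp(-bat / t1_blood)
    dt = t - bat
    inflow = pref * (1.0 - np.exp(-np.clip(dt, 0.0, None) / t1p))
    decay = pref * (1.0 - np.exp(-tau / t1p)) * np.exp(
        -np.clip(dt - tau, 0.0, None) / t1p)
    return np.where(dt < 0, 0.0, np.where(dt < tau, inflow, decay))


def casl_tissue_signal(t, p: KineticParams, tau: float):
    """Tissue Delta-M of the continuous-labeling kinetic model at time ``t``.

    ``t`` is measured from the start of labeling; the readout of a slice at
    post-labeling delay PLD occurs at ``t = tau + PLD (+ slice offset)``.
    Accepts scalars or arrays; vectorized over ``t``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    if tau <= 0:
        raise ValueError("tau must be positive")
    out = casl_signal_arrays(t, p.cbf, p.bat, tau, p.t1_blood, p.t1_tissue,
                             p.m0b)
    return out if out.ndim else float(out)


def macrovascular_signal(t, p: KineticParams, tau: float):
    """Delta-M of labeled blood transiting the voxel inside large vessels."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    ta = p.bat_art
    box = (t >= ta) & (t < ta + tau)
    out = np.where(box, 2.0 * p.m0b * p.abv * np.exp(-t / p.t1_blood), 0.0)
    return out if out.ndim else float(out)


def component_signal(t, p: KineticParams, tau: float):
    """Tissue plus macrovascular Delta-M for one arterial component."""
    s = casl_tissue_signal(t, p, tau)
    if p.abv > 0:
        s = s + macrovascular_signal(t, p, tau)
    return s


def voxel_signal(components: Sequence[KineticParams],
                 timing: AcquisitionTiming,
                 slice_index: int = 0) -> np.ndarray:
    """Summed multi-PLD Delta-M of a voxel fed by several arteries.

    Each PLD is evaluated at the slice's effective readout time
    ``tau + PLD + slice_index * time_per_slice``.
    """
    if not components:
        raise ValueError("at least one arterial component is required")
    if not 0 <= slice_index < timing.n_slices:
        raise ValueError("slice_index out of range")
    t = (timing.tau + np.asarray(timing.plds, dtype=float)
         + slice_index * timing.time_per_slice)
    total = np.zeros_like(t)
    for p in components:
        total += component_signal(t, p, timing.tau)
    return total
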