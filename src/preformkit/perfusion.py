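"""Effective intestinal permeability from closed-loop (Doluisio) perfusion.

A drug solution is perfused into an isolated, ligated intestinal segment and
sampled periodically.  Net water flux across the wall changes the luminal
volume, so each measured concentration C_e is first rescaled to the initial
volume, C_t = C_e * V_t / V_0, which makes the corrected series proportional
to the amount of drug remaining in the lumen.  Luminal disappearance is then
first order, C_t = C_0 * exp(-ka * t), and ka is estimated by nonlinear
regression in concentration space.  Treating the segment as a cylinder of
length L holding the perfusion volume V gives the effective radius
r = sqrt(V / (pi * L)), and the effective permeability follows from the
surface-to-volume ratio of the cylinder: Peff = ka * r / 2 (ka in 1/s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "PerfusionAssay",
    "PerfusionFit",
    "volume_corrected_concentration",
    "fit_first_order",
    "effective_radius",
    "peff_from_ka",
    "analyze_assay",
    "summarize_segments",
]

SEGMENTS = ("duodenum", "jejunum", "ileum", "whole")


@dataclass
class PerfusionAssay:
    """Luminal concentration time course for one animal and segment.

    Times in minutes, concentrations in uM, volumes in mL, length in cm.
    ``v_t`` gives the luminal volume at each sample time; when only the
    initial and final volumes are known, intermediate values are linearly
    interpolated.
    """

    segment: str
    times: np.ndarray
    concentrations_measured: np.ndarray
    v0: float = 10.0
    v_t: np.ndarray | None = None
    v_end: float | None = None
    length_cm: float = 30.0
    perfusion_volume: float = 10.0

    def __post_init__(self) -> None:
        if self.segment not in SEGMENTS:
            raise ValueError(f"segment must be one of {SEGMENTS}")
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations_measured = np.asarray(
            self.concentrations_measured, dtype=float)
        if self.times[0] < 0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing and start >= 0")
        if self.concentrations_measured.shape != self.times.shape:
            raise ValueError("one concentration per time point required")
        if np.any(self.concentrations_measured < 0):
            raise ValueError("concentrations must be >= 0")
        if min(self.v0, self.length_cm, self.perfusion_volume) <= 0:
            raise ValueError("volumes and length must be > 0")
        if self.v_t is not None:
            self.v_t = np.asarray(self.v_t, dtype=float)
            if self.v_t.shape != self.times.shape:
                raise ValueError("one v_t per time point required")
            if np.any(self.v_t <= 0):
                raise ValueError("volumes must be > 0")

    def volumes(self) -> np.ndarray:
        """Per-sample luminal volumes, interpolating the endpoints if needed."""
        if self.v_t is not None:
            return self.v_t
        v_end = self.v0 if self.v_end is None else self.v_end
        span = self.times[-1] - self.times[0]
        return self.v0 + (v_end - self.v0) * (self.times - self.times[0]) / span


@dataclass
class PerfusionFit:
    ka: float  # 1/min
    c0: float  # uM
    r: float  # cm
    peff: float  # cm/s
    sd_peff: float = 0.0
    segment: str = "whole"
    non_decaying: bool = False

    def __post_init__(self) -> None:
        if self.ka < 0:
            raise ValueError("ka must be >= 0")
        if self.c0 <= 0:
            raise ValueError("c0 must be > 0")
        if self.r <= 0:
            raise ValueError("r must be > 0")


def volume_corrected_concentration(c_e, v_t, v0):
    """Rescale measured concentrations to the initial luminal volume.

    C_t = C_e * V_t / V_0: the corrected value is proportional to the drug
    mass remaining in the lumen, removing the bias from net water flux.
    """
    c_e = np.asarray(c_e, dtype=float)
    v_t = np.asarray(v_t, dtype=float)
    if np.any(v_t <= 0) or v0 <= 0:
        raise ValueError("volumes must be > 0")
    out = c_e * v_t / v0
    return float(out) if out.ndim == 0 else out


def fit_first_order(times, c_t, log_space: bool = False) -> tuple[float, float, bool]:
    """Fit C_t = C0 * exp(-ka * t) with ka >= 0.

    Returns (ka [1/min], c0 [uM], non_decaying flag).  The default objective
    is ordinary least squares in concentration space; ``log_space=True``
    switches to log concentrations, appropriate for multiplicative noise.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(c_t, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 time points")
    if np.any(c <= 0):
        raise ValueError("corrected concentrations must be > 0")
    # log-linear start values
    slope, intercept = np.polyfit(t, np.log(c), 1)
    if slope >= 0:
        return 0.0, float(c.mean()), True
    ka0, c00 = -slope, math.exp(intercept)
    if log_space:
        model = lambda tt, ka, c0: np.log(c0) - ka * tt
        ydata = np.log(c)
    else:
        model = lambda tt, ka, c0: c0 * np.exp(-ka * tt)
        ydata = c
    popt, _ = curve_fit(model, t, ydata, p0=[ka0, c00],
                        bounds=([0.0, 1e-12], [np.inf, np.inf]),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    return float(popt[0]), float(popt[1]), False


def effective_radius(length_cm: float, perfusion_volume_mL: float) -> float:
    """Radius (cm) of a cylinder of the given length holding the perfusion
    volume: r = sqrt(V / (pi * L))."""
    if length_cm <= 0 or perfusion_volume_mL <= 0:
        raise ValueError("length and volume must be > 0")
    return math.sqrt(perfusion_volume_mL / (math.pi * length_cm))


def peff_from_ka(ka_per_min: float, r_cm: float) -> float:
    """Peff = r * ka / 2 with ka converted to 1/s; result in cm/s."""
    if ka_per_min < 0:
        raise ValueError("ka must be >= 0")
    if r_cm <= 0:
        raise ValueError("r must be > 0")
    return r_cm * (ka_per_min / 60.0) / 2.0


def analyze_assay(assay: PerfusionAssay, log_space: bool = False) -> PerfusionFit:
    """Full pipeline for one animal: volume correction, first-order fit,
    cylinder radius, Peff."""
    c_t = volume_corrected_concentration(
        assay.concentrations_measured, assay.volumes(), assay.v0)
    ka, c0, flat = fit_first_order(assay.times, c_t, log_space=log_space)
    r = effective_radius(assay.length_cm, assay.perfusion_volume)
    return PerfusionFit(ka=ka, c0=c0, r=r, peff=peff_from_ka(ka, r),
                        segment=assay.segment, non_decaying=flat)


def summarize_segments(fits) -> dict[str, tuple[float, float, int]]:
    """Mean +/- sample sd of Peff (cm/s) per intestinal segment over animals."""
    out: dict[str, tuple[float, float, int]] = {}
    by_segment: dict[str, list[float]] = {}
    for fit in fits:
        by_segment.setdefault(fit.segment, []).append(fit.peff)
    for segment, values in by_segment.items():
        arr = np.asarray(values)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        out[segment] = (float(arr.mean()), sd, int(arr.size))
    return out
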