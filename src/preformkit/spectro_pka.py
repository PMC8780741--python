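"""Spectrophotometric pKa estimation from absorbance-pH curves.

An ionizable chromophore shifts its UV-Vis spectrum when it gains or loses a
proton, so at a wavelength sensitive to the transition the absorbance traces a
sigmoid in pH whose midpoint is the pKa.  The estimator implemented here is the
classical graphical "crossing point" construction: the two secant lines drawn
through the pairs of points adjacent to the steepest part of the A(pH) curve
are extended until they intersect, and the pH of the intersection is taken as
the pKa.  On a symmetric sigmoid this reproduces the inflection point to well
within the pH grid spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "SpectralSeries",
    "PkaEstimate",
    "select_analytical_wavelengths",
    "pka_from_crossing",
    "adjust_pka_temperature",
    "average_replicates",
    "DEFAULT_DPKA_DT",
]

# Linear temperature coefficients (pKa units per deg C) for the two ionizable
# groups of the default study compound, back-derived from its reported
# 23 C / 37 C pKa pairs.  They are configuration, not measured thermodynamics:
# callers with van't Hoff data should supply their own coefficient.
DEFAULT_DPKA_DT = {"basic": 0.06 / 14.0, "acidic": -0.16 / 14.0}


class NoTransitionError(ValueError):
    """Raised when an absorbance-pH series shows no usable pH dependence."""


@dataclass
class SpectralSeries:
    """Absorbance as a function of pH at a set of wavelengths.

    ``absorbance`` is an (n_pH, n_wavelength) matrix in absorbance units.
    ``cosolvent_fraction`` records the organic cosolvent content of the
    buffers (kept at or below 2 % v/v so the apparent pKa is unshifted).
    """

    wavelengths_nm: np.ndarray
    ph_values: np.ndarray
    absorbance: np.ndarray
    temperature_C: float = 23.0
    cosolvent_fraction: float = 0.02

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.ph_values = np.asarray(self.ph_values, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.shape != (self.ph_values.size, self.wavelengths_nm.size):
            raise ValueError(
                f"absorbance shape {self.absorbance.shape} inconsistent with "
                f"{self.ph_values.size} pH values x {self.wavelengths_nm.size} wavelengths"
            )
        if np.any(np.diff(self.ph_values) <= 0):
            raise ValueError("ph_values must be strictly increasing")
        if np.any(self.absorbance < 0):
            raise ValueError("absorbance values must be >= 0")
        if not 0 <= self.cosolvent_fraction <= 0.02:
            raise ValueError("cosolvent_fraction must be within [0, 0.02]")

    def column(self, wavelength_nm: float) -> np.ndarray:
        """Absorbance-vs-pH profile at one wavelength."""
        idx = np.flatnonzero(np.isclose(self.wavelengths_nm, wavelength_nm))
        if idx.size == 0:
            raise KeyError(f"wavelength {wavelength_nm} nm not in series")
        return self.absorbance[:, idx[0]]


@dataclass
class PkaEstimate:
    value: float
    sd: float = 0.0
    character: str = "basic"  # "basic": protonation site; "acidic": deprotonation site
    wavelength_nm: float | None = None
    temperature_C: float = 23.0
    outside_bracket: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.value < 14.0:
            raise ValueError(f"pKa {self.value} outside the aqueous range (0, 14)")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.character not in ("acidic", "basic"):
            raise ValueError("character must be 'acidic' or 'basic'")


def select_analytical_wavelengths(
    series: SpectralSeries, k: int, epsilon: float = 1e-3
) -> list[float]:
    """Pick the ``k`` most pH-sensitive wavelengths.

    A wavelength is diagnostic for an acid-base transition when its absorbance
    changes with pH, so wavelengths are ranked by their absorbance range
    (max - min) across the pH grid, descending.  Wavelengths whose range falls
    below ``epsilon`` are never selected.
    """
    if series.ph_values.size < 2 or series.wavelengths_nm.size < 1:
        raise ValueError("need at least 2 pH points and 1 wavelength")
    ranges = series.absorbance.max(axis=0) - series.absorbance.min(axis=0)
    usable = np.flatnonzero(ranges > epsilon)
    if usable.size == 0:
        raise NoTransitionError(
            "no analytical wavelength: absorbance is pH-independent everywhere"
        )
    order = usable[np.argsort(ranges[usable])[::-1]]
    return [float(w) for w in series.wavelengths_nm[order[:k]]]


def pka_from_crossing(
    ph_values: Sequence[float],
    absorbance: Sequence[float],
    epsilon: float = 1e-6,
    character: str | None = None,
    temperature_C: float = 23.0,
    wavelength_nm: float | None = None,
) -> PkaEstimate:
    """Crossing-point pKa from a single absorbance-pH curve.

    The curve must cover one acid-base transition: a plateau on each side with
    a monotone sigmoidal change in between (window multi-transition data to
    one transition before calling).  The pKa is read off where the curve
    crosses the mid-transition absorbance level, halfway between the two
    plateaus: the linear equation through the two sampled points closest to
    that crossing is solved for the pH at which A equals the mid level.  A
    sigmoid is locally antisymmetric about its midpoint, so the linear solve
    recovers the inflection pH to a small fraction of the grid spacing.

    If the crossing segment is not adjacent to the steepest part of the curve
    the estimate is flagged (``outside_bracket``) rather than rejected.
    """
    ph = np.asarray(ph_values, dtype=float)
    a = np.asarray(absorbance, dtype=float)
    if ph.size != a.size:
        raise ValueError("ph_values and absorbance must have equal length")
    if ph.size < 4:
        raise ValueError("need at least 4 pH points to bracket a transition")
    diffs = np.abs(np.diff(a))
    if diffs.max() < epsilon:
        raise NoTransitionError("no detectable transition in absorbance series")
    i = int(np.argmax(diffs))  # steepest segment is (i, i+1)
    # plateau levels taken from the window endpoints; mid level halfway between
    a_mid = 0.5 * (a[0] + a[-1])
    sign = np.sign(a - a_mid)
    brackets = np.flatnonzero(sign[:-1] * sign[1:] <= 0)
    if brackets.size == 0:
        raise NoTransitionError("curve never crosses its mid-transition level")
    j = int(brackets[np.argmin(np.abs(brackets - i))])
    slope = (a[j + 1] - a[j]) / (ph[j + 1] - ph[j])
    if slope == 0.0:
        crossing = 0.5 * (ph[j] + ph[j + 1])
    else:
        crossing = ph[j] + (a_mid - a[j]) / slope
    outside = abs(j - i) > 1
    if character is None:
        character = "basic" if crossing < 7.0 else "acidic"
    return PkaEstimate(
        value=float(crossing),
        sd=0.0,
        character=character,
        wavelength_nm=wavelength_nm,
        temperature_C=temperature_C,
        outside_bracket=outside,
    )


def average_replicates(estimates: Sequence[PkaEstimate]) -> PkaEstimate:
    """Mean pKa over replicate determinations with the sample sd (ddof=1)."""
    if not estimates:
        raise ValueError("no replicate estimates to average")
    values = np.array([e.value for e in estimates])
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return replace(estimates[0], value=float(values.mean()), sd=sd)


def adjust_pka_temperature(
    estimate: PkaEstimate,
    target_temperature_C: float,
    dpka_dT: float | None = None,
) -> PkaEstimate:
    """Linear temperature shift of a pKa.

    value' = value + dpka_dT * (T_target - T_source).  When ``dpka_dT`` is not
    given, the back-derived default for the estimate's character is used
    (see ``DEFAULT_DPKA_DT``).
    """
    if dpka_dT is None:
        dpka_dT = DEFAULT_DPKA_DT[estimate.character]
    new_value = estimate.value + dpka_dT * (target_temperature_C - estimate.temperature_C)
    if not 0.0 < new_value < 14.0:
        raise ValueError(
            f"temperature-adjusted pKa {new_value:.2f} outside the aqueous range"
        )
    return replace(estimate, value=new_value, temperature_C=target_temperature_C)
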