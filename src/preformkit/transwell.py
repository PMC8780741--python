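"""Apparent permeability from cell-monolayer transport under non-sink conditions.

In a transwell experiment the drug diffuses from the donor to the receiver
compartment across a cell monolayer of area S.  When the receiver
concentration becomes an appreciable fraction of the equilibrium value,
back-flux matters and the simple linear-slope Papp underestimates transport;
the concentration in the receiver instead relaxes exponentially toward the
equilibrium Q_total/(V_receiver + V_donor):

    C_r(t_k) = C_eq + (f * C_r(t_{k-1}) - C_eq) * exp(-Papp*S*(1/Vr + 1/Vd)*dt)

where f = (Vr - Vs)/Vr accounts for replacing each withdrawn sample of volume
Vs with blank buffer.  Sampling also removes drug from the system, so the
recursion here additionally depletes Q_total by the withdrawn mass at each
sampling event; between events it is then the exact solution of the
two-compartment mass-transfer ODE.  Papp is obtained by least-squares fit of
this forward model to the measured receiver time course.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import ttest_ind

__all__ = [
    "TranswellAssay",
    "PappResult",
    "dilution_factor",
    "forward_receiver_series",
    "fit_papp",
    "efflux_ratio",
    "compare_to_reference",
    "compare_groups",
]


@dataclass
class TranswellAssay:
    """One bidirectional-transport run (single replicate, single direction).

    Volumes in mL, membrane area in cm^2, times in minutes, concentrations in
    uM.  ``donor_concentrations`` holds the start and end donor samples;
    ``q_total`` (nmol) is estimated from the initial donor and receiver
    samples when not supplied.
    """

    direction: str  # "A-B" | "B-A"
    v_receiver: float
    v_donor: float
    receiver_concentrations: np.ndarray
    sample_times: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 15.0, 30.0, 60.0, 90.0]))
    membrane_area: float = 4.2
    sample_volume: float = 0.2
    donor_concentrations: tuple[float, float] | None = None
    q_total: float | None = None

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.receiver_concentrations = np.asarray(
            self.receiver_concentrations, dtype=float)
        if self.direction not in ("A-B", "B-A"):
            raise ValueError("direction must be 'A-B' or 'B-A'")
        if min(self.v_receiver, self.v_donor, self.membrane_area) <= 0:
            raise ValueError("volumes and membrane area must be > 0")
        if not 0 <= self.sample_volume < self.v_receiver:
            raise ValueError("sample_volume must be in [0, v_receiver)")
        if np.any(np.diff(self.sample_times) <= 0):
            raise ValueError("sample_times must be strictly increasing")
        if self.receiver_concentrations.shape != self.sample_times.shape:
            raise ValueError("one receiver concentration per sample time required")
        if np.any(self.receiver_concentrations < 0):
            raise ValueError("concentrations must be >= 0")
        if self.q_total is None and self.donor_concentrations is None:
            raise ValueError("supply q_total or donor_concentrations")

    def total_amount(self) -> float:
        """Total drug amount (nmol) in the system at t = 0."""
        if self.q_total is not None:
            return self.q_total
        c_d0 = self.donor_concentrations[0]
        return self.v_donor * c_d0 + self.v_receiver * self.receiver_concentrations[0]

    def mass_balance_deviation(self) -> float | None:
        """Relative deviation of the end-of-run recovery from the initial load.

        Uses the final donor sample plus the predicted-from-measured receiver
        and cumulative sampled mass; None when no end donor sample exists.
        """
        if self.donor_concentrations is None:
            return None
        q0 = self.total_amount()
        c_r = self.receiver_concentrations
        sampled = float(np.sum(c_r * self.sample_volume))
        q_end = (self.donor_concentrations[1] * self.v_donor
                 + c_r[-1] * (self.v_receiver - self.sample_volume) + sampled)
        return abs(q_end - q0) / q0


@dataclass
class PappResult:
    papp: float  # cm/s
    sd: float = 0.0
    n: int = 1
    direction: str = "A-B"
    fit_sse: float = 0.0
    warning: str | None = None

    def __post_init__(self) -> None:
        if self.papp < 0:
            raise ValueError("papp must be >= 0")


def dilution_factor(v_receiver: float, sample_volume: float) -> float:
    """Replacement dilution factor f = (Vr - Vs)/Vr."""
    if not 0 <= sample_volume < v_receiver:
        raise ValueError("need 0 <= sample_volume < v_receiver")
    return (v_receiver - sample_volume) / v_receiver


def forward_receiver_series(assay: TranswellAssay, papp: float,
                            return_masses: bool = False):
    """Predicted receiver concentrations (uM) at the assay's sample times.

    A sampling event (withdraw ``sample_volume``, replace with blank buffer)
    is applied at every listed time, including t = 0; the withdrawn mass is
    removed from the system total, so the recursion conserves mass exactly.
    """
    if papp < 0:
        raise ValueError("papp must be >= 0")
    vr, vd = assay.v_receiver, assay.v_donor
    f = dilution_factor(vr, assay.sample_volume)
    rate = papp * assay.membrane_area * (1.0 / vr + 1.0 / vd)  # 1/s
    q = assay.total_amount()
    c = assay.receiver_concentrations[0]
    times = assay.sample_times
    predicted = np.empty_like(times)
    sampled_masses = []
    for k, t in enumerate(times):
        if k > 0:
            dt = (t - times[k - 1]) * 60.0  # min -> s
            c_eq = q / (vr + vd)
            c = c_eq + (c - c_eq) * math.exp(-rate * dt)
        predicted[k] = c
        # sampling event at t_k: mass leaves, volume replaced with blank
        sampled_masses.append(c * assay.sample_volume)
        q -= c * assay.sample_volume
        c *= f
    if return_masses:
        return predicted, np.asarray(sampled_masses)
    return predicted


def fit_papp(assay: TranswellAssay) -> PappResult:
    """Least-squares Papp (cm/s) from the measured receiver time course."""
    measured = assay.receiver_concentrations
    if measured.size < 4:
        raise ValueError("need at least 3 post-zero sample times")
    warning = None
    if np.all(measured == 0.0):
        return PappResult(papp=0.0, direction=assay.direction, fit_sse=0.0,
                          warning="all receiver concentrations are zero")

    def resid(log_shift: np.ndarray) -> np.ndarray:
        return forward_receiver_series(assay, log_shift[0])[1:] - measured[1:]

    # crude initial slope estimate, clipped into the admissible range
    c_d0 = assay.total_amount() / assay.v_donor
    slope = max((measured[1] - measured[0]) /
                ((assay.sample_times[1] - assay.sample_times[0]) * 60.0), 0.0)
    p0 = max(slope * assay.v_receiver / (assay.membrane_area * max(c_d0, 1e-12)),
             1e-8)
    sol = least_squares(resid, [p0], bounds=([0.0], [np.inf]),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    papp = float(sol.x[0])
    if papp == 0.0:
        warning = "optimum at the nonnegativity bound (papp clipped to 0)"
    dev = assay.mass_balance_deviation()
    if dev is not None and dev > 0.10:
        warning = (warning + "; " if warning else "") + \
            f"mass-balance recovery deviates by {dev:.0%}"
    return PappResult(papp=papp, direction=assay.direction,
                      fit_sse=float(np.sum(sol.fun ** 2)), warning=warning)


def efflux_ratio(papp_ba: float, papp_ab: float) -> float:
    """Papp(B->A) / Papp(A->B); values well below 1 indicate net absorptive
    (carrier-assisted) transport, above 1 net efflux (e.g. P-glycoprotein)."""
    if papp_ab <= 0:
        raise ValueError("papp_ab must be > 0")
    return papp_ba / papp_ab


def compare_to_reference(papp: float, papp_reference: float) -> tuple[str, float]:
    """Permeability class versus the high-permeability reference compound.

    Returns ('high'|'low', papp/papp_reference); the boundary is inclusive.
    """
    if papp_reference <= 0:
        raise ValueError("papp_reference must be > 0")
    ratio = papp / papp_reference
    return ("high" if ratio >= 1.0 else "low"), ratio


def compare_groups(values_a, values_b) -> tuple[float, float, bool]:
    """Two-tailed Welch t test between two Papp replicate groups.

    Returns (t, p, significant at p < 0.05).  Plumbing around the standard
    routine; Welch's form is used because replicate variances are rarely equal
    across directions or cell lines.
    """
    t, p = ttest_ind(np.asarray(values_a, float), np.asarray(values_b, float),
                     equal_var=False)
    return float(t), float(p), bool(p < 0.05)
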