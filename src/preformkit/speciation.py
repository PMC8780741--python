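"""Solubility-pH speciation model for an ordinary ampholyte with salt formation.

The model describes a compound X carrying one basic site (XH+ <-> X + H+,
constant pKa1) and one acidic site (X <-> X- + H+, constant pKa2).  When the
neutral solid saturates the solution, [X] equals the intrinsic solubility S0
and the total dissolved drug follows the Henderson-Hasselbalch ampholyte
profile

    S(pH) = S0 * (1 + 10**(pKa1 - pH) + 10**(pH - pKa2)),

a U-shaped curve in log S.  At sufficiently low pH in the presence of chloride
the hydrochloride salt XH+Cl- becomes the stable solid; its solubility product
Ksp = a(XH+) * a(Cl-) then caps the cation concentration and the common-ion
effect makes solubility *fall* as more HCl (hence chloride) is added.  At each
pH the phase that predicts the lower total solubility is the one actually
saturating, and the two branches meet at pHmax.

Activity corrections use the Davies equation; ionic strength, titrant chloride
and the activity coefficients are solved self-consistently at every pH.  Model
constants are refined against measured (pH, S) data by weighted nonlinear
least squares on log10 S, the standard approach for solubility profiles whose
errors are proportional to the measured value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "SolubilityPoint",
    "SpeciationModel",
    "TitrationPoint",
    "RefinementResult",
    "hh_solubility_ampholyte",
    "salt_branch_solubility",
    "davies_gamma",
    "solubility_at",
    "simulate_titration",
    "refine_model",
    "calculated_solubility_table",
    "ph_max",
]

KW = 1e-14  # water autoprotolysis, 25-37 C approximation


@dataclass
class SolubilityPoint:
    """One measured equilibrium solubility at a buffered pH."""

    ph: float
    solubility: float  # ug/mL
    sd: float = 0.0
    temperature_C: float = 37.0
    chloride_background: float = 0.0  # mol/L chloride contributed by the buffer

    def __post_init__(self) -> None:
        if self.solubility <= 0:
            raise ValueError("solubility must be > 0")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass
class SpeciationModel:
    """Constants of the ampholyte + hydrochloride-salt speciation model.

    s0 is the intrinsic solubility of the neutral species in ug/mL; pka1 the
    basic (cation <-> neutral) constant, pka2 the acidic (neutral <-> anion)
    constant; pksp = -log10 Ksp of XH+Cl- on the mol^2/L^2 scale, or None when
    no salt phase is modelled.  activity_A and activity_b parameterize the
    Davies equation.
    """

    s0: float
    pka1: float
    pka2: float
    pksp: float | None = None
    molecular_weight: float = 404.4
    activity_A: float = 0.509
    activity_b: float = 0.3

    def __post_init__(self) -> None:
        if self.s0 <= 0:
            raise ValueError("s0 must be > 0")
        if not self.pka1 < self.pka2:
            raise ValueError("pka1 (basic) must be below pka2 (acidic)")
        if self.pksp is not None and not math.isfinite(self.pksp):
            raise ValueError("pksp must be finite or None")
        if self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be > 0")

    @property
    def s0_molar(self) -> float:
        return self.s0 / (self.molecular_weight * 1e3)

    @property
    def ksp(self) -> float | None:
        return None if self.pksp is None else 10.0 ** (-self.pksp)


@dataclass
class TitrationPoint:
    ph: float
    ionic_strength: float
    s_calc: float  # ug/mL
    saturating_phase: str  # "neutral" | "salt"
    chloride: float  # mol/L


@dataclass
class RefinementResult:
    model: SpeciationModel
    weighted_sse: float
    iterations: int
    converged: bool
    residuals: np.ndarray = field(repr=False)  # log10(S_meas) - log10(S_calc), all points
    excluded: tuple[float, ...] = ()


def hh_solubility_ampholyte(ph, model: SpeciationModel):
    """Henderson-Hasselbalch ampholyte solubility (no salt, unit activities)."""
    ph = np.asarray(ph, dtype=float)
    s = model.s0 * (1.0 + 10.0 ** (model.pka1 - ph) + 10.0 ** (ph - model.pka2))
    return float(s) if s.ndim == 0 else s


def davies_gamma(ionic_strength: float, charge: int,
                 A: float = 0.509, b: float = 0.3) -> float:
    """Davies activity coefficient: log10 g = -A z^2 (sqrt(I)/(1+sqrt(I)) - b I)."""
    if ionic_strength < 0:
        raise ValueError("ionic strength must be >= 0")
    if ionic_strength == 0 or charge == 0:
        return 1.0
    root = math.sqrt(ionic_strength)
    return 10.0 ** (-A * charge * charge * (root / (1.0 + root) - b * ionic_strength))


def salt_branch_solubility(ph, model: SpeciationModel, chloride: float,
                           gamma: float = 1.0):
    """Total dissolved drug (ug/mL) when the hydrochloride salt saturates.

    The Ksp relation fixes [XH+] = Ksp / (gamma^2 [Cl-]); neutral and anionic
    fractions follow from the two pKa values.
    """
    if model.ksp is None:
        raise ValueError("model has no salt phase (pksp is None)")
    if chloride <= 0:
        raise ValueError("chloride must be > 0 on the salt branch")
    ph = np.asarray(ph, dtype=float)
    cation = model.ksp / (gamma * gamma * chloride)
    total = cation * (1.0 + 10.0 ** (ph - model.pka1)
                      + 10.0 ** (ph - model.pka1) * 10.0 ** (ph - model.pka2))
    s = total * model.molecular_weight * 1e3
    return float(s) if s.ndim == 0 else s


def ph_max(model: SpeciationModel, chloride: float, gamma: float = 1.0,
           lo: float = 0.0, hi: float = 14.0) -> float:
    """pH where the salt and neutral-phase branches intersect (phase switch)."""
    f = lambda p: (salt_branch_solubility(p, model, chloride, gamma)
                   - hh_solubility_ampholyte(p, model))
    return float(brentq(f, lo, hi, xtol=1e-10))


def _speciate_at_ph(model: SpeciationModel, ph: float, *,
                    chloride_background: float = 0.0,
                    fixed_chloride: float | None = None,
                    use_activity: bool = True,
                    i_tol: float = 1e-6, max_iter: int = 200):
    """Solve the saturation equilibrium at one pH.

    Chloride is either held at ``fixed_chloride`` or built self-consistently
    from the buffer background plus the strong-acid (HCl) titrant required by
    the charge balance; above neutrality the titrant is NaOH and contributes
    sodium instead.  The ionic strength / activity-coefficient loop iterates
    to a fixed point (change below ``i_tol`` mol/L).
    """
    h = 10.0 ** (-ph)
    oh = KW / h
    ionic = 0.0
    gamma1 = 1.0
    for iteration in range(max_iter):
        if use_activity:
            gamma1 = davies_gamma(ionic, 1, model.activity_A, model.activity_b)
        # neutral-solid branch: [X] = s0 (molar), gamma0 taken as 1
        x = model.s0_molar
        cation_n = x * 10.0 ** (model.pka1 - ph) / gamma1
        anion_n = x * 10.0 ** (ph - model.pka2) / gamma1
        if fixed_chloride is not None:
            cl_n = fixed_chloride
        else:
            titrant = h + cation_n - oh - anion_n  # HCl demand from charge balance
            cl_n = chloride_background + max(0.0, titrant)
        phase, cation, anion, cl = "neutral", cation_n, anion_n, cl_n
        x_total = x + cation_n + anion_n
        ksp = model.ksp
        if ksp is not None and cl_n > 0 and gamma1 * gamma1 * cation_n * cl_n > ksp:
            # salt is the stable solid; on this branch both drug ions scale as
            # 1/[Cl-], so the chloride charge balance reduces to a quadratic
            phase = "salt"
            if fixed_chloride is not None:
                cl = fixed_chloride
            else:
                alpha = chloride_background + h - oh
                beta = (ksp / (gamma1 * gamma1)) * (
                    1.0 - 10.0 ** (2.0 * ph - model.pka1 - model.pka2))
                disc = alpha * alpha + 4.0 * beta
                cl = (alpha + math.sqrt(disc)) / 2.0 if disc > 0 else 0.0
                cl = max(cl, chloride_background)
                if cl <= 0:
                    raise RuntimeError(
                        f"no chloride available for the salt phase at pH {ph:.2f}")
            cation = ksp / (gamma1 * gamma1 * cl)
            x = cation * gamma1 * 10.0 ** (ph - model.pka1)
            anion = x * 10.0 ** (ph - model.pka2) / gamma1
            x_total = x + cation + anion
        sodium = 0.0
        if fixed_chloride is None:
            # NaOH titrant above the self-buffered point: charge balance deficit
            deficit = (oh + anion + cl) - (h + cation)
            sodium = max(0.0, deficit)
        counter = chloride_background  # background Cl- arrives with a +1 counter-ion
        ionic_new = 0.5 * (h + oh + cl + sodium + cation + anion + counter)
        if not use_activity:
            ionic = ionic_new
            break
        if abs(ionic_new - ionic) < i_tol:
            ionic = ionic_new
            break
        # damped update: the bare fixed point can oscillate at extreme pH
        ionic = 0.5 * (ionic + ionic_new)
    else:
        raise RuntimeError(f"ionic-strength iteration did not converge at pH {ph:.2f}")
    s_ug = x_total * model.molecular_weight * 1e3
    return TitrationPoint(ph=float(ph), ionic_strength=float(ionic),
                          s_calc=float(s_ug), saturating_phase=phase,
                          chloride=float(cl))


def solubility_at(model: SpeciationModel, ph: float, *,
                  chloride_background: float = 0.0,
                  fixed_chloride: float | None = None,
                  use_activity: bool = True) -> float:
    """Equilibrium solubility (ug/mL) at one pH from the full engine."""
    return _speciate_at_ph(model, ph, chloride_background=chloride_background,
                           fixed_chloride=fixed_chloride,
                           use_activity=use_activity).s_calc


def simulate_titration(model: SpeciationModel, ph_start: float = 0.0,
                       ph_end: float = 13.0, step: float = 0.2, *,
                       chloride_background: float = 0.0,
                       fixed_chloride: float | None = None,
                       use_activity: bool = True) -> list[TitrationPoint]:
    """Sweep the saturated suspension from ph_start to ph_end in fixed pH steps.

    At each grid pH the saturating solid is chosen (salt when its predicted
    solubility undercuts the neutral branch and chloride is available), the
    titrant counter-ions are folded into the chloride and ionic-strength
    balance, and the gamma-corrected solubility is recorded.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    n = int(round((ph_end - ph_start) / step))
    grid = ph_start + step * np.arange(n + 1)
    return [
        _speciate_at_ph(model, p, chloride_background=chloride_background,
                        fixed_chloride=fixed_chloride, use_activity=use_activity)
        for p in grid
    ]


def calculated_solubility_table(model: SpeciationModel,
                                ph_list: Sequence[float], *,
                                ph_start: float = 0.0, ph_end: float = 13.0,
                                step: float = 0.2,
                                **engine_kwargs) -> list[tuple[float, float]]:
    """S_calc at requested pH values, interpolated (log-linearly) on the
    titration grid."""
    points = simulate_titration(model, ph_start, ph_end, step, **engine_kwargs)
    grid = np.array([p.ph for p in points])
    logs = np.log10([p.s_calc for p in points])
    out = []
    for ph in ph_list:
        if ph < grid[0] - 1e-9 or ph > grid[-1] + 1e-9:
            raise ValueError(f"pH {ph} outside simulated range "
                             f"[{grid[0]:.2f}, {grid[-1]:.2f}]")
        out.append((float(ph), float(10.0 ** np.interp(ph, grid, logs))))
    return out


_PARAM_ORDER = ("s0", "pksp", "pka1", "pka2")


def _log_sigma(point: SolubilityPoint, sigma_floor: float) -> float:
    # propagate sd(S) to sd(log10 S); floor avoids infinite weights
    if point.sd > 0:
        return max(point.sd / (point.solubility * math.log(10.0)), sigma_floor)
    return sigma_floor


def refine_model(points: Sequence[SolubilityPoint], initial: SpeciationModel,
                 free_parameters: Iterable[str] = ("s0", "pksp"), *,
                 exclude_ph: Sequence[float] = (),
                 sigma_floor: float = 0.02,
                 use_activity: bool = True) -> RefinementResult:
    """Weighted nonlinear least-squares refinement of the speciation model.

    Minimizes sum w_i (log10 S_meas,i - log10 S_calc,i)^2 over the requested
    free parameters (any of s0, pksp, pka1, pka2), with weights 1/sigma^2 in
    log space.  s0 is refined on the log10 scale.  Points whose pH appears in
    ``exclude_ph`` are masked out of the objective but their residuals are
    still reported.
    """
    free = [p for p in _PARAM_ORDER if p in set(free_parameters)]
    unknown = set(free_parameters) - set(_PARAM_ORDER)
    if unknown:
        raise ValueError(f"unknown free parameters: {sorted(unknown)}")
    if "pksp" in free and initial.pksp is None:
        raise ValueError("cannot refine pksp: initial model has no salt phase")
    points = list(points)
    if len(points) < 3:
        raise ValueError("need at least 3 solubility points")
    mask = np.array([not any(abs(p.ph - e) < 1e-6 for e in exclude_ph)
                     for p in points])
    if int(mask.sum()) < len(free):
        raise ValueError("fewer included points than free parameters")

    sigmas = np.array([_log_sigma(p, sigma_floor) for p in points])
    log_meas = np.log10([p.solubility for p in points])

    def unpack(theta: np.ndarray) -> SpeciationModel:
        kwargs = {}
        for name, value in zip(free, theta):
            kwargs[name] = 10.0 ** value if name == "s0" else value
        return replace(initial, **kwargs)

    def all_residuals(model: SpeciationModel) -> np.ndarray:
        out = np.empty(len(points))
        for i, p in enumerate(points):
            s = solubility_at(model, p.ph,
                              chloride_background=p.chloride_background,
                              use_activity=use_activity)
            out[i] = log_meas[i] - math.log10(s)
        return out

    def objective(theta: np.ndarray) -> np.ndarray:
        try:
            r = all_residuals(unpack(theta))
        except (ValueError, RuntimeError):
            return np.full(int(mask.sum()), 1e6)
        return (r / sigmas)[mask]

    theta0 = np.array([
        math.log10(initial.s0) if name == "s0" else getattr(initial, name)
        for name in free
    ])
    sol = least_squares(objective, theta0, method="trf",
                        xtol=1e-10, ftol=1e-10, gtol=1e-10)
    refined = unpack(sol.x)
    residuals = all_residuals(refined)
    sse = float(np.sum((residuals[mask] / sigmas[mask]) ** 2))
    return RefinementResult(
        model=refined,
        weighted_sse=sse,
        iterations=int(sol.nfev),
        converged=bool(sol.status > 0),
        residuals=residuals,
        excluded=tuple(float(p.ph) for p, m in zip(points, mask) if not m),
    )
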