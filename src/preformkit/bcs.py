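"""Provisional BCS classification from dose number and permeability evidence.

The Biopharmaceutics Classification System places a drug in one of four
quadrants.  Solubility is judged by the dose number

    Do = D / (V0 * Cs)

with D the dose (mg), V0 the 250 mL reference volume of aqueous medium and Cs
the solubility (mg/mL) at a given pH: the dose dissolves in a glass of water
at every relevant pH iff max Do <= 1 ("high solubility").  Permeability is
judged per experimental method against a high-permeability reference compound
(conventionally metoprolol) measured under the same conditions; the overall
permeability class is the majority over methods, with the full evidence list
retained.  Class 1 = high/high, 2 = low solubility/high permeability,
3 = high/low, 4 = low/low.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "DoseInputs",
    "BCSRecord",
    "FabsCorrelation",
    "dose_number",
    "highest_dose_from_weight",
    "solubility_class",
    "permeability_class",
    "bcs_class",
    "predict_fabs",
]

REFERENCE_VOLUME_ML = 250.0
# regulatory pH window for solubility classification (inclusive)
SOLUBILITY_PH_RANGE = (1.2, 6.8)


@dataclass
class DoseInputs:
    dose_mg: float
    cs_mg_per_mL: float
    v0_mL: float = REFERENCE_VOLUME_ML

    def __post_init__(self) -> None:
        if min(self.dose_mg, self.cs_mg_per_mL, self.v0_mL) <= 0:
            raise ValueError("dose, solubility and reference volume must be > 0")


@dataclass
class BCSRecord:
    do_by_ph: dict[float, float]
    solubility_class: str
    permeability_class: str
    bcs_class: int
    evidence: list[tuple[str, str]] = field(default_factory=list)
    dose_convention: str = "weight-based"

    def __post_init__(self) -> None:
        expected = bcs_class(self.solubility_class, self.permeability_class)
        if self.bcs_class != expected:
            raise ValueError(
                f"bcs_class {self.bcs_class} inconsistent with "
                f"({self.solubility_class}, {self.permeability_class})")


@dataclass
class FabsCorrelation:
    """Caller-supplied permeability -> fraction-absorbed correlation.

    Forms: 'exponential-saturation', Fabs = 100 * (1 - exp(-k * Peff));
    'logistic', Fabs = 100 / (1 + 10**(slope * (x50 - log10 Peff))).
    Coefficients come from a laboratory's own validated reference-compound
    calibration and are configuration, not outputs of this package.
    """

    form: str
    parameters: dict[str, float]
    source_model: str = "caco2"  # "caco2" | "rat"

    _REQUIRED = {"exponential-saturation": ("k",), "logistic": ("x50", "slope")}

    def __post_init__(self) -> None:
        if self.form not in self._REQUIRED:
            raise ValueError(f"unknown correlation form {self.form!r}")
        missing = [p for p in self._REQUIRED[self.form] if p not in self.parameters]
        if missing:
            raise ValueError(f"missing correlation parameters: {missing}")


def dose_number(inputs: DoseInputs) -> float:
    """Do = D / (V0 * Cs), dimensionless."""
    return inputs.dose_mg / (inputs.v0_mL * inputs.cs_mg_per_mL)


def highest_dose_from_weight(dose_mg_per_kg: float, body_weight_kg: float) -> float:
    """Weight-based dose in mg (e.g. lowest efficacious animal dose scaled to
    a 70 kg adult)."""
    if dose_mg_per_kg <= 0 or body_weight_kg <= 0:
        raise ValueError("dose per kg and body weight must be > 0")
    return dose_mg_per_kg * body_weight_kg


def solubility_class(do_by_ph: dict[float, float],
                     ph_range: tuple[float, float] | None = SOLUBILITY_PH_RANGE
                     ) -> str:
    """'high' iff the worst-case (largest) Do within the pH window is <= 1.

    ``ph_range=None`` uses every supplied pH.  If no pH falls inside the
    window, all supplied values are used rather than failing.
    """
    if not do_by_ph:
        raise ValueError("empty dose-number map")
    values = do_by_ph
    if ph_range is not None:
        inside = {p: d for p, d in do_by_ph.items()
                  if ph_range[0] - 1e-9 <= p <= ph_range[1] + 1e-9}
        if inside:
            values = inside
    return "high" if max(values.values()) <= 1.0 else "low"


def permeability_class(evidence: dict[str, tuple[float, float]]
                       ) -> tuple[str, list[tuple[str, str]]]:
    """Aggregate per-method permeability classes by majority vote.

    ``evidence`` maps method name -> (measured permeability, reference
    permeability by the same method).  Ties go to 'low' (conservative).
    Returns (overall class, [(method, class), ...]).
    """
    if not evidence:
        raise ValueError("no permeability evidence")
    per_method = []
    for method, (value, reference) in evidence.items():
        if reference <= 0:
            raise ValueError(f"reference permeability for {method} must be > 0")
        per_method.append((method, "high" if value >= reference else "low"))
    n_high = sum(1 for _, c in per_method if c == "high")
    overall = "high" if n_high * 2 > len(per_method) else "low"
    return overall, per_method


def bcs_class(solubility: str, permeability: str) -> int:
    """Four-quadrant class: (high, high)->1, (low, high)->2, (high, low)->3,
    (low, low)->4."""
    table = {("high", "high"): 1, ("low", "high"): 2,
             ("high", "low"): 3, ("low", "low"): 4}
    try:
        return table[(solubility, permeability)]
    except KeyError:
        raise ValueError("classes must be 'high' or 'low'") from None


def predict_fabs(peff: float, correlation: FabsCorrelation) -> float:
    """Predicted fraction absorbed (%) from a permeability value, clamped to
    [0, 100]."""
    if peff < 0:
        raise ValueError("peff must be >= 0")
    if correlation.form == "exponential-saturation":
        fabs = 100.0 * (1.0 - math.exp(-correlation.parameters["k"] * peff))
    else:  # logistic in log10 Peff
        if peff == 0.0:
            return 0.0
        x = math.log10(peff)
        p = correlation.parameters
        fabs = 100.0 / (1.0 + 10.0 ** (p["slope"] * (p["x50"] - x)))
    return min(100.0, max(0.0, fabs))
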