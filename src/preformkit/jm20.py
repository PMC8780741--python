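"""Published study inputs for JM-20, the default compound of this package.

JM-20 (3-ethoxycarbonyl-2-methyl-4-(2-nitrophenyl)-4,11-dihydro-1H-pyrido
[2,3-b][1,5]benzodiazepine) is a hybrid benzodiazepine-dihydropyridine
neuroprotective candidate and an ordinary ampholyte: a basic ring nitrogen
(pKa1 5.48 at 23 C) and an acidic dihydropyridine carbon (pKa2 10.49 at
23 C), shifting to 5.54 and 10.33 at the 37 C of the solubility experiments.

This module collects the small published data tables the analyses consume:
the six shake-flask solubility measurements, the weight-based dose, and the
buffer chloride backgrounds.  Only the pH 1.2 medium (HCl/KCl) contributes
chloride from the buffer itself; the acetate and phosphate media do not, and
the chloride reaching the hydrochloride-salt equilibrium there is the HCl
titrant demanded by the charge balance.
"""

from __future__ import annotations

from .bcs import DoseInputs, dose_number, highest_dose_from_weight
from .speciation import SolubilityPoint, SpeciationModel

MOLECULAR_WEIGHT = 404.4  # g/mol

PKA1_23C, PKA2_23C = 5.48, 10.49
PKA1_37C, PKA2_37C = 5.54, 10.33

DOSE_MG_PER_KG = 2.0  # lowest efficacious dose in animal studies
BODY_WEIGHT_KG = 70.0
DOSE_MG = highest_dose_from_weight(DOSE_MG_PER_KG, BODY_WEIGHT_KG)  # 140 mg

# pH 1.2 medium is 0.05 M KCl + ~0.013 M HCl (USP formulation)
CHLORIDE_PH12 = 0.063

# shake-flask solubility at 37 C: (pH, mean ug/mL, sd ug/mL)
SOLUBILITY_TABLE = (
    (1.2, 9.18, 0.16),
    (3.5, 12.72, 0.83),
    (4.0, 25.38, 0.66),
    (4.5, 30.84, 1.29),
    (6.8, 11.30, 0.69),
    (7.4, 12.64, 0.36),
)

# the pH 1.2 point is not describable by the hydrochloride-salt model and is
# excluded from refinement by default (its residual is still reported)
DEFAULT_EXCLUDE_PH = (1.2,)


def solubility_points() -> list[SolubilityPoint]:
    """The measured solubility profile as model-ready points."""
    return [
        SolubilityPoint(ph=ph, solubility=s, sd=sd,
                        chloride_background=CHLORIDE_PH12 if ph == 1.2 else 0.0)
        for ph, s, sd in SOLUBILITY_TABLE
    ]


def initial_model(s0: float = 20.0, pksp: float = 7.0) -> SpeciationModel:
    """Starting speciation model for refinement: pKa fixed at the 37 C
    values, s0 and pksp free."""
    return SpeciationModel(s0=s0, pka1=PKA1_37C, pka2=PKA2_37C, pksp=pksp,
                           molecular_weight=MOLECULAR_WEIGHT)


def dose_numbers(dose_mg: float = DOSE_MG) -> dict[float, float]:
    """Do at each measured pH from the shake-flask solubilities."""
    return {
        ph: dose_number(DoseInputs(dose_mg=dose_mg, cs_mg_per_mL=s / 1000.0))
        for ph, s, _ in SOLUBILITY_TABLE
    }
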