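"""Seeded synthetic datasets with the statistical structure of each assay.

Each generator simulates one experiment of the preformulation workflow —
absorbance-pH spectra, shake-flask solubility profiles, bidirectional
transwell transport, and closed-loop intestinal perfusion — from known true
parameters, and returns the dataset together with a ``truth`` dictionary
recording those parameters.  Recovery tests read the truth record only, never
the estimator under test.

Noise defaults follow assay practice: multiplicative lognormal for
concentrations and solubilities (assay CVs are proportional to the measured
value) and additive Gaussian for absorbances.  One global seed fans out to
per-assay substreams by stable hashing of the assay name, so adding a
generator call never perturbs the streams of the others.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np

from .perfusion import PerfusionAssay, effective_radius
from .speciation import SolubilityPoint, SpeciationModel, solubility_at
from .spectro_pka import SpectralSeries
from .transwell import TranswellAssay, forward_receiver_series

__all__ = [
    "GeneratorConfig",
    "substream",
    "gen_spectra",
    "gen_solubility",
    "gen_transwell",
    "gen_perfusion",
    "write_truth",
]


@dataclass
class GeneratorConfig:
    seed: int = 0
    noise_model: str = "multiplicative-lognormal"
    noise_sd: float = 0.0
    replicates: int = 3
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_model not in ("multiplicative-lognormal", "additive-gaussian"):
            raise ValueError("unknown noise model")


def substream(seed: int, name: str) -> np.random.Generator:
    """Child RNG for one assay, derived from the global seed and a stable
    hash of the assay name."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


def write_truth(path, truth: dict) -> None:
    """Sidecar JSON with the generator's true parameters."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)


# default analytical wavelengths and transition amplitudes of the synthetic
# two-transition chromophore (AU); signs differ so the two transitions are
# distinguishable at every wavelength
_SPECTRA_BANDS = {262.0: (0.55, 0.45, -0.25), 316.0: (0.30, -0.22, 0.35),
                  355.0: (0.15, 0.28, 0.18)}


def gen_spectra(pka1: float, pka2: float,
                wavelengths=None, ph_grid=None,
                noise_sd: float = 0.0, seed: int = 0,
                bands: dict | None = None,
                temperature_C: float = 23.0) -> tuple[SpectralSeries, dict]:
    """Absorbance-pH series with sigmoidal transitions at pka1 and pka2.

    Per wavelength: A(pH) = baseline + amp1 * frac1(pH) + amp2 * frac2(pH)
    with frac_i = 1/(1 + 10**(pKa_i - pH)), plus additive Gaussian noise.
    ``bands`` maps wavelength -> (baseline, amp1, amp2); pass amp = 0 to make
    a wavelength blind to a transition.
    """
    if not pka1 < pka2:
        raise ValueError("pka1 must be below pka2")
    bands = dict(_SPECTRA_BANDS) if bands is None else bands
    if wavelengths is None:
        wavelengths = sorted(bands)
    ph_grid = (np.arange(2.0, 13.01, 0.5) if ph_grid is None
               else np.asarray(ph_grid, dtype=float))
    if ph_grid[0] > pka1 - 1.5 or ph_grid[-1] < pka2 + 1.5:
        import warnings
        warnings.warn("pH grid does not fully span both transitions",
                      stacklevel=2)
    rng = substream(seed, "spectra")
    a = np.empty((ph_grid.size, len(wavelengths)))
    for j, wl in enumerate(wavelengths):
        baseline, amp1, amp2 = bands.get(float(wl), (0.2, 0.0, 0.0))
        frac1 = 1.0 / (1.0 + 10.0 ** (pka1 - ph_grid))
        frac2 = 1.0 / (1.0 + 10.0 ** (pka2 - ph_grid))
        a[:, j] = baseline + amp1 * frac1 + amp2 * frac2
    if noise_sd > 0:
        a = a + rng.normal(0.0, noise_sd, size=a.shape)
    a = np.clip(a, 0.0, None)
    series = SpectralSeries(wavelengths_nm=np.asarray(wavelengths, float),
                            ph_values=ph_grid, absorbance=a,
                            temperature_C=temperature_C)
    truth = {"pka1": pka1, "pka2": pka2, "noise_sd": noise_sd, "seed": seed,
             "bands": {str(k): list(v) for k, v in bands.items()}}
    return series, truth


def gen_solubility(model: SpeciationModel, ph_list,
                   noise_sd_log: float = 0.0, n_reps: int = 3,
                   seed: int = 0) -> tuple[list[SolubilityPoint], dict]:
    """Shake-flask solubility measurements around the model's true profile.

    S_meas = S_calc(pH) * 10**eps with eps ~ Normal(0, noise_sd_log) per
    replicate; the reported point is the replicate mean with the replicate
    sample sd.
    """
    rng = substream(seed, "solubility")
    points = []
    for ph in ph_list:
        s_true = solubility_at(model, float(ph))
        reps = s_true * 10.0 ** rng.normal(0.0, noise_sd_log, size=n_reps)
        sd = float(reps.std(ddof=1)) if n_reps > 1 else 0.0
        points.append(SolubilityPoint(ph=float(ph),
                                      solubility=float(reps.mean()), sd=sd))
    truth = {"model": asdict(model), "noise_sd_log": noise_sd_log,
             "n_reps": n_reps, "seed": seed}
    return points, truth


def _integrate_transwell(assay: TranswellAssay, papp: float,
                         dt_s: float = 0.5) -> np.ndarray:
    """Fine-step Euler integration of the two-compartment system with
    instantaneous sampling events; independent of the interval recursion."""
    vr, vd = assay.v_receiver, assay.v_donor
    q = assay.total_amount()
    m_r = assay.receiver_concentrations[0] * vr
    out = np.empty_like(assay.sample_times)
    t = assay.sample_times[0]
    for k, t_k in enumerate(assay.sample_times):
        while t < t_k - 1e-9:
            step = min(dt_s / 60.0, t_k - t)
            c_r, c_d = m_r / vr, (q - m_r) / vd
            m_r += papp * assay.membrane_area * (c_d - c_r) * step * 60.0
            t += step
        out[k] = m_r / vr
        removed = out[k] * assay.sample_volume
        q -= removed
        m_r -= removed
    return out


def gen_transwell(papp_true: float, *, efflux_asymmetry: float = 1.0,
                  v_receiver: float = 2.0, v_donor: float = 2.0,
                  membrane_area: float = 4.2, sample_volume: float = 0.2,
                  sample_times=(0.0, 15.0, 30.0, 60.0, 90.0),
                  donor_concentration: float = 100.0,
                  noise_sd: float = 0.0, seed: int = 0,
                  route: str = "recursion"
                  ) -> tuple[TranswellAssay, TranswellAssay, dict]:
    """Bidirectional transwell pair: A-B at papp_true, B-A at
    papp_true * efflux_asymmetry.

    ``route`` selects the forward model: 'recursion' (interval-exact
    two-compartment solution) or 'ode' (independent fine-step integrator, for
    tests that must avoid the inverse crime of generating and fitting with
    the same code path).  Noise is multiplicative lognormal on the receiver
    concentrations.
    """
    if papp_true < 0:
        raise ValueError("papp_true must be >= 0")
    rng = substream(seed, "transwell")
    assays = []
    for direction, papp in (("A-B", papp_true),
                            ("B-A", papp_true * efflux_asymmetry)):
        assay = TranswellAssay(
            direction=direction, v_receiver=v_receiver, v_donor=v_donor,
            receiver_concentrations=np.zeros(len(sample_times)),
            sample_times=np.asarray(sample_times, float),
            membrane_area=membrane_area, sample_volume=sample_volume,
            donor_concentrations=(donor_concentration, float("nan")))
        if route == "recursion":
            clean = forward_receiver_series(assay, papp)
        elif route == "ode":
            clean = _integrate_transwell(assay, papp)
        else:
            raise ValueError("route must be 'recursion' or 'ode'")
        noisy = clean * np.exp(rng.normal(0.0, noise_sd, size=clean.shape)) \
            if noise_sd > 0 else clean
        # end-of-run donor concentration from the in-system mass balance
        _, sampled = forward_receiver_series(assay, papp, return_masses=True)
        q_end = assay.total_amount() - float(np.sum(sampled[:-1]))
        c_d_end = (q_end - noisy[-1] * v_receiver) / v_donor
        assays.append(TranswellAssay(
            direction=direction, v_receiver=v_receiver, v_donor=v_donor,
            receiver_concentrations=np.clip(noisy, 0.0, None),
            sample_times=np.asarray(sample_times, float),
            membrane_area=membrane_area, sample_volume=sample_volume,
            donor_concentrations=(donor_concentration, float(c_d_end))))
    truth = {"papp_true": papp_true, "efflux_asymmetry": efflux_asymmetry,
             "noise_sd": noise_sd, "seed": seed, "route": route}
    return assays[0], assays[1], truth


def gen_perfusion(peff_true: float, *, segment: str = "jejunum",
                  length_cm: float = 30.0, v0: float = 10.0,
                  water_flux_rate: float = 0.0,
                  times=(5.0, 10.0, 15.0, 20.0, 25.0, 30.0),
                  c0: float = 100.0, noise_sd: float = 0.0,
                  seed: int = 0) -> tuple[PerfusionAssay, dict]:
    """Closed-loop perfusion time course with known true permeability.

    The cylinder geometry fixes ka = 2 * Peff / r (converted to 1/min); the
    luminal mass decays first order while the luminal volume shrinks linearly
    at ``water_flux_rate`` (mL/min).  Measured concentrations are
    mass / V_t with multiplicative lognormal noise.
    """
    if peff_true < 0:
        raise ValueError("peff_true must be >= 0")
    t = np.asarray(times, dtype=float)
    r = effective_radius(length_cm, v0)
    ka_per_min = 2.0 * peff_true / r * 60.0
    v_t = v0 - water_flux_rate * t
    if np.any(v_t <= 0):
        raise ValueError("luminal volume reaches zero within the schedule")
    mass = c0 * v0 * np.exp(-ka_per_min * t)  # uM * mL = nmol
    c_e = mass / v_t
    if noise_sd > 0:
        rng = substream(seed, "perfusion")
        c_e = c_e * np.exp(rng.normal(0.0, noise_sd, size=c_e.shape))
    assay = PerfusionAssay(segment=segment, times=t,
                           concentrations_measured=c_e, v0=v0, v_t=v_t,
                           length_cm=length_cm, perfusion_volume=v0)
    truth = {"peff_true": peff_true, "ka_per_min": ka_per_min, "r": r,
             "length_cm": length_cm, "v0": v0,
             "water_flux_rate": water_flux_rate, "c0": c0,
             "noise_sd": noise_sd, "seed": seed}
    return assay, truth
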