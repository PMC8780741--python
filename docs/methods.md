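# Methods

`preformkit` implements the four quantitative stages of an early
preformulation study of an ionizable drug candidate — spectrophotometric pKa
estimation, solubility–pH speciation modelling, cell-monolayer and in situ
intestinal permeability, and provisional BCS classification — as a single
tested pipeline. The default compound configuration is JM-20, an ordinary
ampholyte (basic benzodiazepine ring nitrogen, acidic dihydropyridine
carbon), but every stage is parameterized and works for any compound with
the same model structure.

## Spectrophotometric pKa (`spectro_pka`)

An ionizable chromophore's absorbance at a pH-sensitive wavelength follows a
sigmoid in pH with its midpoint at the pKa. Analytical wavelengths are
selected by the absorbance *range* across the pH grid (a wavelength is
diagnostic when its absorbance changes with pH, not when it is merely
large). The estimator is a deterministic version of the graphical
crossing-point reading: the two plateau levels are taken from the window
endpoints, and the linear equation through the two sampled points closest to
where the curve crosses the mid-transition level is solved for the crossing
pH. Because a sigmoid is locally antisymmetric about its inflection, the
linear solve is nearly unbiased: on noiseless sigmoids sampled every 0.5 pH
units the worst-case error over pKa 3–11 is 0.013 pH units (0.009 at 0.25
spacing). An alternative construction — intersecting the two secant segments
that flank the steepest segment — was evaluated and rejected: the flanking
secants are nearly horizontal on the plateaus, making their intersection
ill-conditioned, with errors up to a full grid step.

Curves containing two transitions must be windowed to one transition before
calling the estimator; the pipeline splits at the midpoint between the two
expected pKa values. Replicates are estimated independently and averaged;
the reported sd is the sample sd (ddof = 1).

Temperature adjustment is linear, `pKa(T2) = pKa(T1) + (dpKa/dT)(T2 − T1)`,
with a caller-supplied coefficient. The shipped defaults (+0.06/14 per °C
for the basic site, −0.16/14 per °C for the acidic site) are back-derived
from the JM-20 23 °C/37 °C pairs (5.48 → 5.54 and 10.49 → 10.33) and are
configuration, not measured thermodynamics.

## Solubility–pH speciation (`speciation`)

**Model.** Neutral species X with basic constant pKa1 and acidic constant
pKa2. When the neutral solid saturates, [X] = S0 (intrinsic solubility) and

    S(pH) = S0 (1 + 10^(pKa1−pH) + 10^(pH−pKa2)),

the Henderson–Hasselbalch ampholyte profile. With chloride present, the
hydrochloride salt XH⁺Cl⁻ can become the stable solid at low pH; its
solubility product Ksp = γ²[XH⁺][Cl⁻] caps the cation, giving

    S_salt(pH) = (Ksp/(γ²[Cl⁻])) (1 + 10^(pH−pKa1) + 10^(2pH−pKa1−pKa2)).

At each pH the reported solubility is the branch of the lower value (phase
rule); the branches cross at pHmax. Activity corrections use the Davies
equation, log10 γ = −A z² (√I/(1+√I) − b I), A = 0.509, b = 0.3 — the
standard choice in solubility-refinement software when the activity model is
otherwise unspecified. The neutral species is assigned γ = 1.

**Chloride and ionic strength.** The titration simulator sweeps pH 0 → 13 in
0.2 steps. At each grid pH the chloride available to the salt equilibrium is
the buffer background plus the strong-acid (HCl) titrant demanded by the
charge balance [H⁺] + [XH⁺] + [Na⁺] = [OH⁻] + [Cl⁻] + [X⁻]; above the
self-buffered point the titrant is NaOH and contributes sodium instead. On
the salt branch both drug ions scale as 1/[Cl⁻], so the chloride balance
reduces to a quadratic solved in closed form. Ionic strength is iterated to
a fixed point (tolerance 1e−6 mol/L) with 0.5 damping, which stabilizes the
extreme-pH region where the bare iteration can oscillate. This
charge-balance chloride scheme reproduces the qualitative common-ion
signature: in the salt region solubility *falls* as pH falls below ~2,
because each further HCl addition supplies more of the common ion.

**Refinement.** Model constants (any of log10 S0, pKsp, pKa1, pKa2) are fit
to measured (pH, S) points by weighted nonlinear least squares on log10 S,
weights 1/σ² with σ = sd/(S ln 10) floored at 0.02 log units so tiny
reported sds cannot dominate. The optimizer is SciPy's trust-region
reflective `least_squares` with finite-difference Jacobians (convergence
tolerances 1e−10); S0 is refined on the log scale to keep it positive.
Per-point exclusion masks remove points from the objective while still
reporting their residuals — the default JM-20 configuration excludes the
pH 1.2 point, which the hydrochloride-salt model cannot describe (the model
predicts ~0.1 µg/mL there against a measured 9.18, a two-order-of-magnitude
residual that is reported, not hidden).

With pKa fixed at the 37 °C values and S0/pKsp free, refinement against the
six bundled JM-20 measurements gives S0 = 11.79 µg/mL and pKsp = 8.04.
Aggregation and complexation equilibria are not modelled; the model
dataclass is the extension point if they ever are.

## Transwell permeability (`transwell`)

Under non-sink conditions the receiver concentration relaxes exponentially
toward the equilibrium Q_total/(V_r + V_d); each sampling event multiplies
the receiver concentration by f = (V_r − V_s)/V_r (sample replaced by blank
buffer). The forward model applies the interval recursion

    C_r(t_k) = C_eq + (f·C_r(t_{k−1}) − C_eq)·exp(−Papp·S·(1/V_r + 1/V_d)·Δt)

with one deliberate strengthening: the withdrawn mass C_r·V_s is subtracted
from Q_total at every sampling event (including t = 0). With that
bookkeeping the recursion is the *exact* solution of the two-compartment
mass-transfer ODE with instantaneous sampling events — it conserves mass to
machine precision and agrees with an independent stiff-solver integration to
better than 0.5 %. The constant-Q_total form would drift from the true
system by a few percent over a five-sample schedule at realistic
permeabilities, precisely the error the recursion exists to avoid.

Papp is the single nonnegative parameter of a least-squares fit of this
forward model to the measured receiver series; an all-zero series returns
Papp = 0 with a warning rather than an error. Q_total defaults to
V_d·C_d(0) + V_r·C_r(0); the end-of-run donor sample is used only as a
recovery check, flagged when the mass balance deviates by more than 10 %.
Compartment volumes default to 2.0 mL/2.0 mL with a 4.2 cm² membrane,
0.2 mL samples at 0/15/30/60/90 min and 100 µM donor loading — the study's
assay geometry where published, plainly labelled fixture values where not.
Efflux ratio is Papp(B→A)/Papp(A→B); classification is against a
high-permeability reference compound measured under the same conditions
(boundary inclusive). Direction/cell-line comparisons use a two-tailed
Welch t test at p < 0.05 (Welch rather than pooled-variance, since replicate
variances across directions are rarely equal).

## Closed-loop perfusion (`perfusion`)

Measured luminal concentrations are first corrected for net water flux,
C_t = C_e·V_t/V_0, which makes the corrected series proportional to the
remaining luminal mass; the printed form of this correction is typeset
ambiguously in the source literature and this mass-preserving reading is the
standard Doluisio correction. When only endpoint volumes are known, V_t is
interpolated linearly. Disappearance is fit as C_t = C0·e^(−ka·t) by
nonlinear regression in concentration space (a log-space option exists for
multiplicative noise). Geometry: the segment is a cylinder holding the
perfusion volume (default 10 mL), r = √(V/(πL)), and Peff = r·ka/2 with ka
in 1/s. Segment summaries are mean ± sample sd over animals; no
mixed-effects modelling.

A structural validation: with water flux but zero permeation the corrected
series is constant and the fitted ka is numerically zero (< 1e−9/min).

## BCS classification (`bcs`)

Dose number Do = D/(V0·Cs) with V0 = 250 mL. The solubility class is
decided by the worst (largest) Do over the regulatory pH window 1.2–6.8
(boundary Do = 1 counts as high); pH values outside the window (e.g. 7.4)
are reported but do not decide the class, a deliberate resolution of the
divergent agency definitions. The dose convention is recorded alongside the
result; the JM-20 configuration uses the weight-based 2 mg/kg × 70 kg =
140 mg. Permeability is classified per method against that method's
reference value and aggregated by majority vote (ties conservatively low),
with the full per-method evidence list retained. Fraction-absorbed
prediction is a parameterized correlation (exponential-saturation or
logistic in log10 Peff) whose coefficients must come from the caller's own
validated calibration; no coefficients ship with the package.

## Synthetic data (`synthetic`)

Generators emulate each assay with embedded truth records: two-transition
sigmoidal spectra (additive Gaussian noise, as for absorbances); U-shaped
solubility profiles from the full speciation engine (multiplicative
lognormal noise, matching proportional assay CVs); bidirectional transwell
time courses via either the interval recursion or an independent fine-step
Euler integrator (so recovery tests can avoid the inverse crime of
generating and fitting with the same code path); and first-order luminal
depletion with linear water flux. One global seed fans out to per-assay
substreams by CRC-32 hashing of the assay name, so streams are stable under
addition of new generators. Defaults mirror the study conditions: 100 µM
loading, 0/15/30/60/90 min transwell schedule, 10 mL loop sampled every
5 min for 30 min, n = 3–4 replicates.

What the generators do *not* emulate: chromatographic quantification error
structure, inter-laboratory variability, monolayer integrity drift,
luminal degradation or binding, and polymorph/supersaturation kinetics in
solubility. Passing recovery tests therefore demonstrates correctness of
the estimators under the stated noise models, not robustness to those
real-data pathologies.

## Numerical choices and problem sizes

- Titration grid 0.2 pH; calculated tables interpolate log-linearly between
  grid points (interpolation error ~3e−4 relative, verified against a
  half-step simulation).
- Refinement convergence: SciPy TRF with xtol = ftol = gtol = 1e−10;
  reported `converged` reflects optimizer status.
- Simulation studies in the test suite use 100 seeds per scenario at the
  assay noise levels (2 % transwell, 3 % perfusion, 0.05 log-unit
  solubility); each replicate is a small least-squares problem, so the full
  suite runs in a few seconds.
- Degenerate inputs: flat absorbance, all-zero receiver series, constant
  perfusion series and empty dose-number maps all resolve to explicit
  errors, warnings or zero estimates as documented on each function.

## Known limitations

- The half-height pKa estimator assumes plateau coverage on both sides of a
  transition; strongly overlapping transitions (ΔpKa < ~2) would bias both
  estimates and are not handled.
- The speciation engine models one salt (chloride) and no aggregates,
  complexes or cosolvent corrections; buffers enter only through their
  chloride contribution and a 1:1 ionic-strength term.
- The transwell model treats the monolayer as a single barrier without
  paracellular/transcellular decomposition, metabolism or binding.
- Perfusion fits are per-animal; inter-animal variance is summarized, not
  modelled hierarchically.
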