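# Methods

## Scope and model

`bindspec` quantifies the interaction of a small-molecule quencher with a
fluorescent protein (the canonical case: a drug binding bovine serum albumin)
from titration spectroscopy. The analysis chain is:

1. **Quenching fits.** Fluorescence intensity is read at a single analysis
   wavelength — by default the emission maximum of the quencher-free
   spectrum (≈344 nm for BSA excited at 280 nm) — not integrated over the
   band. The Stern–Volmer regression

   F₀/F = 1 + K_sv·[Q]

   is fit by ordinary least squares over all points including [Q] = 0, with
   a *free* intercept; an intercept deviating from 1 by more than 0.05 is
   recorded as a warning rather than constrained away, because the deviation
   is diagnostic of model misfit. The bimolecular quenching rate constant is
   K_q = K_sv/τ₀ with τ₀ = 10⁻⁸ s by default (the accepted unquenched
   lifetime scale for serum albumin); both τ₀ and the diffusion limit are
   overridable.

2. **Binding constant and stoichiometry.** The double-logarithmic (modified
   Stern–Volmer) regression

   log₁₀((F₀−F)/F) = log₁₀K_b + n·log₁₀[Q]

   yields K_b = 10^intercept and n = slope. The [Q] = 0 point is necessarily
   excluded (log 0), as is any point with F₀ − F ≤ 0; exclusion counts are
   reported on the fit object and in the run log. Base-10 logarithms and the
   2.303 conversion factor are used throughout for consistency with the
   conventional presentation of these equations.

3. **Mechanism call.** Static quenching (ground-state complex) is inferred
   only when K_sv decreases *strictly monotonically* with temperature AND
   every K_q exceeds the diffusion-controlled limit (default 2×10¹⁰
   L mol⁻¹ s⁻¹); dynamic quenching requires the strict opposite pattern;
   everything else — ties, non-monotonic trends, mixed evidence — is
   `ambiguous`. Strictness is a deliberate conservative evidence standard.

4. **Thermodynamics.** log₁₀K_b is regressed on 1/T (van't Hoff);
   ΔH° = −2.303·R·slope, ΔS° = 2.303·R·intercept, with R fixed at exactly
   8.314 J mol⁻¹ K⁻¹. ΔG° is reported from ΔH° − T·ΔS° with the
   −RT ln K_b route shown alongside as a cross-check column
   (kcal conversions use the thermochemical calorie, 4184 J). Note that
   because 2.303 is a rounded ln 10, the two ΔG° routes agree to ≈0.02%
   (not machine precision) even on exactly van't-Hoff-consistent inputs.
   Force classification is a pure sign lookup: (ΔH°<0, ΔS°<0) → hydrogen
   bonding + van der Waals; (>0, >0) → hydrophobic; (<0, >0) →
   electrostatic; anything touching zero or (>0, <0) → indeterminate.

5. **Inner-filter correction** F_corr = F_obs·e^((A_ex+A_em)/2) is optional
   (applied per titration point when an absorbance titration is supplied)
   and the run log records whether it was applied, since published analyses
   frequently leave this ambiguous.

6. **CD unmixing.** A far-UV CD spectrum is modelled as a convex combination
   of four basis spectra (α-helix, β, turn, random). Fractions are found by
   least squares on the probability simplex: active-set non-negative least
   squares on the design matrix augmented with a sum-to-one row weighted 10⁶
   above the data scale, followed by exact renormalisation of the
   non-negative solution (a correction below solver precision). This gives
   exact recovery on vertex and interior admissible combinations and hard —
   not clipped — simplex constraints under noise. Default fit window
   200–260 nm, where the diagnostic backbone bands (209/222 nm helix minima,
   ~200 nm coil minimum) live. An ill-conditioned basis (condition number
   > 10⁸) attaches a warning rather than failing.

7. **Band analysis.** IR difference spectra are pointwise subtractions on a
   shared grid (optional interpolation of the reference). Band peaks (amide
   I window 1600–1700 cm⁻¹; amide II 1500–1580 cm⁻¹, a symmetric window
   about the ~1540 cm⁻¹ band) are refined below the grid spacing by a
   three-point parabolic fit around the grid maximum — chosen over
   centroiding because reported amide peak positions carry two decimals,
   implying sub-grid precision. Edge maxima fall back to the window edge
   with a warning. The UV absorbance trend at 278 nm is advisory evidence
   only (rising absorbance is consistent with static quenching); the
   mechanism verdict remains owned by the quenching stage.

## Synthetic generator: what it emulates and what it does not

The generator exists so every stage can be validated by parameter recovery.
Its generative quenching law is

F = F₀ / (1 + K_b·Qⁿ)

chosen because it makes *both* fitted relations exact simultaneously (with
K_sv = K_b when n = 1), giving a clean recovery surface. Ligand depletion
(free vs. total quencher) is ignored — as it is in the fitted equations
themselves. Emission spectra are Gaussian lineshapes (default centre 344 nm,
width 30 nm) whose peak height carries the quenching; temperature dependence
of K_b follows the integrated van't Hoff relation, so (ΔH°, ΔS°) round-trip
exactly through generation and refitting. Default study conditions: 15 μM
protein, quencher 0–120 μM in 15 μM steps, temperatures (288, 298, 308) K,
excitation 280 nm. Noise, when enabled, is i.i.d. Gaussian per grid point
(sd as a fraction of F₀ for emission, in mdeg for CD); real instrument noise
is neither white nor homoscedastic, and no photophysics (lifetimes, FRET,
collisional kinetics) is simulated — so passing recovery tests demonstrates
correctness of the estimators under the stated model, not robustness to
every real-data pathology.

The CD basis set shipped in code (`canonical_cd_basis`) is **synthetic**:
sums of Gaussian lobes placed at the qualitative band positions of the four
structure classes. Instrument-vendor reference sets are proprietary and
percentages derived from real spectra by such black-box estimators are not
reproducible targets; only the unmixing mechanics are validated, by
synthetic recovery. β is kept in the basis even though albumin-style fits
often return 0% for it. Users supply their own calibrated basis file for
real work.

The bundled IR fixture uses Lorentzian amide bands (HWHM 10 cm⁻¹) at
1640.63/1535.60 cm⁻¹ (free) and 1647.59/1539.50 cm⁻¹ (bound) on a 0.5 cm⁻¹
grid — narrow enough that the two bands do not pull each other's apparent
maxima beyond the parabolic-refinement tolerance.

## Numerical choices and degenerate inputs

- Axes are normalised ascending on load (IR spectra conventionally plotted
  descending are stored ascending); duplicated axis values are rejected.
- Intensity extraction is linear interpolation, exact on grid hits;
  out-of-range queries raise rather than extrapolate.
- A perfectly flat F₀/F series returns K_sv = 0 with intercept at the common
  ratio rather than a 0/0 regression.
- All regressions are `scipy.stats.linregress` OLS; standard errors are the
  usual OLS slope/intercept errors, with no further error propagation
  (ΔC_p-resolved van't Hoff and nonlinear Stern–Volmer models are out of
  scope).
- Determinism: every stochastic step takes an explicit seed
  (`numpy.random.default_rng`, no global state); rerunning a report from
  identical config and inputs is byte-identical.

## Problem sizes

Validation studies use the study-scale defaults: 9-point titrations at three
temperatures, a 12-point (K_b, n) truth grid, 200-seed noisy-recovery
replicates for CD and Stern–Volmer coverage checks, 61-point CD grids and
601-point IR grids. The full suite runs in a few seconds.

## Known limitations

- Single-wavelength intensity reading assumes the emission maximum does not
  shift during titration; a shifting maximum would bias K_sv.
- The simplex unmixing inherits the usual ambiguity of near-collinear basis
  sets; the conditioning warning flags but does not resolve it.
- The mechanism classifier is a rule table over two features; combined
  static+dynamic quenching (upward-curving Stern–Volmer) is not modelled.
- Published thermodynamic tables are often internally inconsistent with
  their own rounded binding constants; the van't Hoff stage reports what the
  supplied (T, K_b) data imply, nothing else.
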