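"""Synthetic spectra with known ground truth for every analysis stage.

The generative quenching law is ``F = F0 / (1 + Kb * Q**n)``.  With this
choice the Stern–Volmer relation ``F0/F = 1 + Ksv*Q`` (with ``Ksv = Kb`` when
``n = 1``) and the double-logarithmic binding relation
``log10((F0-F)/F) = log10(Kb) + n*log10(Q)`` both hold exactly, so the fitting
stages can be validated by exact parameter recovery.  Ligand depletion
(free vs. total quencher) is deliberately ignored, matching the fitted
equations themselves.

Emission spectra are Gaussian lineshapes centred near 344 nm, the tryptophan
emission maximum of serum albumin excited at 280 nm; the peak height carries
the quenching signal while the shape stays fixed, emulating quenching with an
unchanged emission maximum.  Temperature dependence of the binding constant
follows the integrated van't Hoff relation, so enthalpy/entropy recovery can
be tested end to end.  Default temperatures are (288, 298, 308) K and default
quencher concentrations run 0–120 μM against 15 μM protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidCompositionError, InvalidInputError, OrderingError
from .spectra import Spectrum, TitrationPoint, TitrationSeries

GAS_CONSTANT = 8.314  # J mol^-1 K^-1

#: Default simulated temperatures (K).
DEFAULT_TEMPERATURES = (288.0, 298.0, 308.0)

#: Default quencher concentrations, mol/L: 0 to 120 uM in 15 uM steps.
DEFAULT_QUENCHER_CONCS = tuple(np.arange(0.0, 121.0, 15.0) * 1e-6)

DEFAULT_PROTEIN_CONC = 15e-6  # mol/L
DEFAULT_EXCITATION_NM = 280.0

STRUCTURE_NAMES = ("alpha_helix", "beta", "turn", "random")


@dataclass(frozen=True)
class QuenchingGroundTruth:
    """Generative parameters for a quenching titration.

    ``kb_per_T`` maps temperature (K) to the binding constant (L/mol);
    ``noise_sd`` is the per-point Gaussian noise standard deviation expressed
    as a fraction of ``f0_amplitude``.
    """

    kb_per_T: dict[float, float]
    n: float = 1.0
    f0_amplitude: float = 1000.0
    emission_center: float = 344.0
    emission_width: float = 30.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if any(kb <= 0 for kb in self.kb_per_T.values()):
            raise InvalidInputError("all binding constants must be > 0")
        if self.n <= 0:
            raise InvalidInputError("stoichiometry n must be > 0")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")
        if self.emission_width <= 0:
            raise InvalidInputError("emission_width must be > 0")


@dataclass(frozen=True)
class ThermoGroundTruth:
    """Van't Hoff generative parameters: ΔH° (J/mol), ΔS° (J mol⁻¹ K⁻¹)."""

    dH: float
    dS: float
    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES

    def __post_init__(self):
        if len(set(self.temperatures)) < 2:
            raise InvalidInputError("need >= 2 distinct reference temperatures")


def kb_from_vant_hoff(truth: ThermoGroundTruth, temperature: float) -> float:
    """Binding constant implied by (ΔH°, ΔS°) at one temperature.

    Evaluates ``Kb = 10**(-dH/(2.303*R*T) + dS/(2.303*R))`` with
    R = 8.314 J mol⁻¹ K⁻¹ — the integrated van't Hoff relation in base-10
    form, the exact inverse of the van't Hoff regression.
    """
    if temperature <= 0:
        raise InvalidInputError("temperature must be > 0 K")
    exponent = (-truth.dH / (2.303 * GAS_CONSTANT * temperature)
                + truth.dS / (2.303 * GAS_CONSTANT))
    return float(10.0 ** exponent)


def quenching_truth_from_thermo(
    thermo: ThermoGroundTruth, **kwargs
) -> QuenchingGroundTruth:
    """Build a quenching truth whose Kb(T) obeys the van't Hoff relation."""
    kb_per_T = {T: kb_from_vant_hoff(thermo, T) for T in thermo.temperatures}
    return QuenchingGroundTruth(kb_per_T=kb_per_T, **kwargs)


def _emission_axis() -> np.ndarray:
    # 300-450 nm at 1 nm pitch; includes the 344 nm maximum as a grid point
    return np.arange(300.0, 451.0, 1.0)


def simulate_quenching_titration(
    truth: QuenchingGroundTruth,
    temperature: float,
    quencher_concs=DEFAULT_QUENCHER_CONCS,
    protein_conc: float = DEFAULT_PROTEIN_CONC,
    excitation_wavelength: float = DEFAULT_EXCITATION_NM,
    axis: np.ndarray | None = None,
) -> TitrationSeries:
    """Simulate one emission titration at a given temperature.

    The noiseless peak intensity follows ``F = F0/(1 + Kb*Q**n)`` exactly;
    each spectrum is a Gaussian lineshape scaled to F, with optional additive
    Gaussian noise of sd ``noise_sd * f0_amplitude`` per grid point.  The same
    truth and seed always produce a bit-identical series.
    """
    if temperature not in truth.kb_per_T:
        raise InvalidInputError(
            f"no ground-truth Kb at {temperature} K; "
            f"available: {sorted(truth.kb_per_T)}"
        )
    concs = np.asarray(list(quencher_concs), dtype=float)
    if concs.size < 3 or concs[0] != 0 or np.any(np.diff(concs) <= 0):
        raise OrderingError(
            "quencher concentrations must start at 0 and be strictly increasing "
            "with >= 3 points"
        )
    kb = truth.kb_per_T[temperature]
    if axis is None:
        axis = _emission_axis()
    lineshape = np.exp(
        -0.5 * ((axis - truth.emission_center) / truth.emission_width) ** 2
    )
    rng = np.random.default_rng(
        np.random.SeedSequence([truth.seed, int(round(temperature * 1000))])
    )
    points = []
    for q in concs:
        f_peak = truth.f0_amplitude / (1.0 + kb * q ** truth.n)
        signal = f_peak * lineshape
        if truth.noise_sd > 0:
            signal = signal + rng.normal(
                0.0, truth.noise_sd * truth.f0_amplitude, size=axis.size
            )
        points.append(
            TitrationPoint(q, Spectrum(axis.copy(), signal, "emission"))
        )
    return TitrationSeries(
        protein_conc=protein_conc,
        temperature=temperature,
        excitation_wavelength=excitation_wavelength,
        points=tuple(points),
    )


# ---------------------------------------------------------------------------
# Circular dichroism


def _gaussian(axis, center, width):
    return np.exp(-0.5 * ((axis - center) / width) ** 2)


def canonical_cd_basis(axis: np.ndarray | None = None):
    """A synthetic far-UV CD basis set for the four structure classes.

    This is a documented stand-in constructed from sums of Gaussian lobes that
    reproduce the qualitative band positions of protein CD reference spectra:
    the α-helix with its double negative minimum near 209 and 222 nm and
    strong positive band near 193 nm; β-sheet with a single negative lobe near
    218 nm and positive near 196 nm; the turn class with a weak positive band
    near 205 nm; and the random coil with its deep negative band near 198 nm.
    Amplitudes are in mdeg at fixture scale.  It exists so the unmixing stage
    can be validated by exact recovery; it is not a calibrated reference set
    and carries no claim about real proteins.
    """
    from .cd import BasisSet  # local import to avoid a cycle

    if axis is None:
        axis = np.arange(200.0, 261.0, 1.0)
    axis = np.asarray(axis, dtype=float)
    components = {
        "alpha_helix": (
            60.0 * _gaussian(axis, 193.0, 8.0)
            - 35.0 * _gaussian(axis, 209.0, 8.0)
            - 33.0 * _gaussian(axis, 222.0, 9.0)
        ),
        "beta": (
            40.0 * _gaussian(axis, 196.0, 7.0)
            - 25.0 * _gaussian(axis, 218.0, 10.0)
        ),
        "turn": (
            12.0 * _gaussian(axis, 205.0, 9.0)
            - 6.0 * _gaussian(axis, 225.0, 12.0)
            + 8.0 * _gaussian(axis, 240.0, 10.0)
        ),
        "random": (
            -45.0 * _gaussian(axis, 198.0, 9.0)
            + 6.0 * _gaussian(axis, 218.0, 12.0)
        ),
    }
    return BasisSet(axis=axis, components=components)


def simulate_cd_spectrum(
    fractions, basis, noise_sd: float = 0.0, seed: int = 0
) -> Spectrum:
    """CD spectrum as a linear combination of basis components plus noise.

    ``fractions`` is a sequence of four values ordered (alpha_helix, beta,
    turn, random) or a mapping from those names; they must be non-negative and
    sum to 1 within 1e-9.  ``noise_sd`` is in mdeg.
    """
    if isinstance(fractions, dict):
        fractions = [fractions.get(name, 0.0) for name in STRUCTURE_NAMES]
    frac = np.asarray(list(fractions), dtype=float)
    if frac.size != len(STRUCTURE_NAMES):
        raise InvalidCompositionError(
            f"expected {len(STRUCTURE_NAMES)} fractions, got {frac.size}"
        )
    if np.any(frac < 0):
        raise InvalidCompositionError(f"fractions must be non-negative: {frac}")
    if abs(frac.sum() - 1.0) > 1e-9:
        raise InvalidCompositionError(
            f"fractions must sum to 1 within 1e-9, got {frac.sum()!r}"
        )
    signal = np.zeros_like(basis.axis)
    for f, name in zip(frac, STRUCTURE_NAMES):
        signal = signal + f * basis.components[name]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=signal.size)
    return Spectrum(basis.axis.copy(), signal, "cd_ellipticity_mdeg")


# ---------------------------------------------------------------------------
# Absorbance / IR bands


def simulate_band_spectrum(
    center: float,
    width: float,
    amplitude: float,
    axis: np.ndarray,
    seed: int = 0,
    noise_sd: float = 0.0,
    kind: str = "ir_absorbance",
    baseline: float = 0.0,
) -> Spectrum:
    """Single Lorentzian band on a grid, with optional additive noise.

    The noiseless curve peaks at the grid point nearest ``center``; used as
    the fixture for amide-band peak-shift detection and UV band trends.
    """
    if width <= 0:
        raise InvalidInputError("band width must be > 0")
    axis = np.asarray(axis, dtype=float)
    signal = baseline + amplitude / (1.0 + ((axis - center) / width) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=axis.size)
    return Spectrum(axis, signal, kind)


def simulate_uv_titration(
    quencher_concs=DEFAULT_QUENCHER_CONCS,
    base_absorbance: float = 0.30,
    absorbance_per_molar: float = 2000.0,
    center: float = 278.0,
    width: float = 18.0,
    protein_conc: float = DEFAULT_PROTEIN_CONC,
    temperature: float = 298.0,
    axis: np.ndarray | None = None,
) -> TitrationSeries:
    """UV absorbance titration with a band near 278 nm rising linearly in Q.

    Emulates the ground-state complexation signature: absorbance of the
    aromatic band grows with added ligand.  Set ``absorbance_per_molar = 0``
    for the unchanged-spectra (dynamic-consistent) control.
    """
    concs = np.asarray(list(quencher_concs), dtype=float)
    if concs.size < 3 or concs[0] != 0 or np.any(np.diff(concs) <= 0):
        raise OrderingError(
            "quencher concentrations must start at 0 and be strictly increasing"
        )
    if axis is None:
        axis = np.arange(240.0, 321.0, 1.0)
    points = []
    for q in concs:
        amp = base_absorbance + absorbance_per_molar * q
        spec = simulate_band_spectrum(
            center, width, amp, axis, noise_sd=0.0, kind="absorbance"
        )
        points.append(TitrationPoint(q, spec))
    return TitrationSeries(
        protein_conc=protein_conc,
        temperature=temperature,
        excitation_wavelength=DEFAULT_EXCITATION_NM,
        points=tuple(points),
    )
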