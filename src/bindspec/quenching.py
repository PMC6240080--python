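"""Fluorescence-quenching analysis: inner-filter correction, Stern–Volmer and
double-logarithmic binding fits, and the static/dynamic mechanism call.

The Stern–Volmer regression ``F0/F = 1 + Ksv*[Q]`` yields the quenching
constant Ksv (L/mol); dividing by the unquenched fluorophore lifetime τ₀
(default 10⁻⁸ s for serum albumin) gives the bimolecular quenching rate
constant Kq.  Kq far above the diffusion-controlled limit (~2×10¹⁰
L mol⁻¹ s⁻¹) together with Ksv falling as temperature rises indicates static
(ground-state complex) quenching; Kq at or below the limit with Ksv rising
indicates dynamic (collisional) quenching.

The modified Stern–Volmer (double-log) regression
``log10((F0-F)/F) = log10(Kb) + n*log10[Q]`` yields the binding constant Kb
and the number of binding sites n.  Base-10 logarithms are used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (
    DegenerateSignalError,
    InsufficientDataError,
    InvalidInputError,
)
from .spectra import TitrationSeries, extract_intensity

DEFAULT_TAU0 = 1e-8  # s, unquenched lifetime assumed for serum albumin
DEFAULT_DIFFUSION_LIMIT = 2e10  # L mol^-1 s^-1, maximum diffusion rate constant

#: |intercept - 1| above which the Stern–Volmer fit records a deviation warning.
INTERCEPT_WARN_TOL = 0.05


@dataclass(frozen=True)
class QuenchingFit:
    """Stern–Volmer fit result at one temperature; ``kq = ksv / tau0``."""

    ksv: float
    ksv_se: float
    intercept: float
    r_squared: float
    tau0: float
    temperature: float
    warnings: tuple[str, ...] = ()

    def __post_init__(self):
        if self.tau0 <= 0:
            raise InvalidInputError("tau0 must be > 0 s")
        if self.ksv_se < 0:
            raise InvalidInputError("ksv_se must be >= 0")

    @property
    def kq(self) -> float:
        """Bimolecular quenching rate constant, L mol⁻¹ s⁻¹."""
        return self.ksv / self.tau0


@dataclass(frozen=True)
class BindingFit:
    """Double-log binding fit: Kb (L/mol) and stoichiometry n."""

    kb: float
    n: float
    log10_kb_se: float
    r_squared: float
    temperature: float
    points_used: int
    points_excluded: int = 0

    def __post_init__(self):
        if self.kb <= 0:
            raise InvalidInputError("Kb must be > 0")
        if self.points_used < 2:
            raise InsufficientDataError("binding fit needs >= 2 points")


@dataclass(frozen=True)
class MechanismCall:
    """Static/dynamic/ambiguous verdict with the evidence behind it."""

    verdict: str
    ksv_trend: str
    kq_exceeds_diffusion_limit: bool
    evidence: tuple[str, ...]


def correct_inner_filter(f_obs, a_ex, a_em):
    """Inner-filter-effect correction ``F_corr = F_obs * exp((A_ex + A_em)/2)``.

    ``a_ex`` and ``a_em`` are the sample absorbances at the excitation and
    emission wavelengths; both must be non-negative.  Accepts scalars or
    arrays and applies the correction pointwise.
    """
    a_ex = np.asarray(a_ex, dtype=float)
    a_em = np.asarray(a_em, dtype=float)
    if np.any(a_ex < 0) or np.any(a_em < 0):
        raise InvalidInputError("absorbances must be >= 0")
    result = np.asarray(f_obs, dtype=float) * np.exp((a_ex + a_em) / 2.0)
    return float(result) if result.ndim == 0 else result


def _series_to_points(series, wavelength):
    if isinstance(series, TitrationSeries):
        if wavelength is None:
            wavelength = series.reference_spectrum().peak_position()
        concs, intensities = extract_intensity(series, wavelength)
        return concs, intensities, series.temperature
    concs, intensities = series
    return np.asarray(concs, float), np.asarray(intensities, float), np.nan


def inner_filter_corrected_points(
    series: TitrationSeries,
    absorbance_series: TitrationSeries,
    wavelength: float | None = None,
):
    """Extract intensities with per-point inner-filter correction applied.

    ``absorbance_series`` must cover the same quencher concentrations; the
    correction uses its absorbance at the excitation wavelength of ``series``
    and at the analysis (emission) wavelength.  Returns ``(concs, F_corr)``
    ready to pass to :func:`fit_stern_volmer` / :func:`fit_binding`.
    """
    if wavelength is None:
        wavelength = series.reference_spectrum().peak_position()
    concs, f_obs = extract_intensity(series, wavelength)
    abs_concs = absorbance_series.quencher_concs
    if not np.array_equal(concs, abs_concs):
        raise InvalidInputError(
            "absorbance titration concentrations do not match the emission "
            f"titration: {abs_concs} vs {concs}"
        )
    a_ex = np.array(
        [p.spectrum.value_at(series.excitation_wavelength)
         for p in absorbance_series.points]
    )
    a_em = np.array(
        [p.spectrum.value_at(wavelength) for p in absorbance_series.points]
    )
    return concs, correct_inner_filter(f_obs, a_ex, a_em)


def fit_stern_volmer(
    series,
    tau0: float = DEFAULT_TAU0,
    wavelength: float | None = None,
    temperature: float | None = None,
) -> QuenchingFit:
    """Ordinary least squares of F0/F on [Q], including the Q=0 point.

    ``series`` is a :class:`TitrationSeries` (intensity read at ``wavelength``,
    defaulting to the emission maximum of the quencher-free spectrum) or a
    pre-extracted ``(concs, intensities)`` pair, e.g. after inner-filter
    correction.  The intercept is left free; a warning is recorded when it
    deviates from 1 by more than 0.05.
    """
    if tau0 <= 0:
        raise InvalidInputError("tau0 must be > 0 s")
    concs, intensities, series_temp = _series_to_points(series, wavelength)
    if temperature is None:
        temperature = series_temp
    if concs.size < 3:
        raise InsufficientDataError(
            f"Stern-Volmer fit needs >= 3 points, got {concs.size}"
        )
    if np.any(intensities <= 0):
        raise DegenerateSignalError(
            "fluorescence intensity must be > 0 at every titration point"
        )
    f0 = intensities[0]
    ratio = f0 / intensities
    if np.allclose(ratio, ratio[0]):
        # no quenching: flat line, slope 0, intercept at the common ratio
        slope, intercept, se, r_squared = 0.0, float(ratio[0]), 0.0, 1.0
    else:
        res = stats.linregress(concs, ratio)
        slope, intercept = float(res.slope), float(res.intercept)
        se, r_squared = float(res.stderr), float(res.rvalue) ** 2
    warnings = ()
    if abs(intercept - 1.0) > INTERCEPT_WARN_TOL:
        warnings = (
            f"Stern-Volmer intercept {intercept:.4f} deviates from 1 by more "
            f"than {INTERCEPT_WARN_TOL}; possible model misfit",
        )
    return QuenchingFit(
        ksv=slope,
        ksv_se=se,
        intercept=intercept,
        r_squared=r_squared,
        tau0=tau0,
        temperature=float(temperature),
        warnings=warnings,
    )


def fit_binding(
    series,
    wavelength: float | None = None,
    temperature: float | None = None,
) -> BindingFit:
    """Double-log regression of log10((F0-F)/F) on log10[Q].

    The Q=0 reference point is necessarily excluded (log 0 undefined), as is
    any point with F0 - F <= 0; exclusion counts are reported on the result.
    ``n`` is the slope and ``Kb = 10**intercept``.
    """
    concs, intensities, series_temp = _series_to_points(series, wavelength)
    if temperature is None:
        temperature = series_temp
    if concs.size < 3:
        raise InsufficientDataError(
            f"binding fit needs >= 3 titration points, got {concs.size}"
        )
    if intensities[0] <= 0:
        raise DegenerateSignalError("reference intensity F0 must be > 0")
    f0 = intensities[0]
    usable = (concs > 0) & (f0 - intensities > 0) & (intensities > 0)
    excluded = int(concs.size - usable.sum())
    if usable.sum() < 2:
        raise InsufficientDataError(
            f"binding fit needs >= 2 usable points after exclusions, "
            f"got {int(usable.sum())} ({excluded} excluded)"
        )
    x = np.log10(concs[usable])
    y = np.log10((f0 - intensities[usable]) / intensities[usable])
    res = stats.linregress(x, y)
    return BindingFit(
        kb=float(10.0 ** res.intercept),
        n=float(res.slope),
        log10_kb_se=float(res.intercept_stderr),
        r_squared=float(res.rvalue) ** 2,
        temperature=float(temperature),
        points_used=int(usable.sum()),
        points_excluded=excluded,
    )


def classify_mechanism(
    fits, diffusion_limit: float = DEFAULT_DIFFUSION_LIMIT
) -> MechanismCall:
    """Static/dynamic call from Ksv temperature trend and Kq magnitude.

    A verdict of ``static`` requires Ksv strictly decreasing with temperature
    and every Kq above the diffusion limit; ``dynamic`` requires Ksv strictly
    increasing and no Kq above the limit; every other combination is
    ``ambiguous``.  Ties in the trend count as non-monotonic.
    """
    fits = sorted(fits, key=lambda f: f.temperature)
    if len(fits) < 2:
        raise InvalidInputError("mechanism call needs fits at >= 2 temperatures")
    temps = [f.temperature for f in fits]
    if len(set(temps)) != len(temps):
        raise InvalidInputError(f"duplicate temperatures in fits: {temps}")
    ksv = [f.ksv for f in fits]
    if all(b < a for a, b in zip(ksv, ksv[1:])):
        trend = "decreasing"
    elif all(b > a for a, b in zip(ksv, ksv[1:])):
        trend = "increasing"
    else:
        trend = "non-monotonic"
    exceeds = all(f.kq > diffusion_limit for f in fits)
    evidence = [f"Ksv vs temperature trend: {trend} "
                f"({', '.join(f'{t:.0f} K: {k:.4g}' for t, k in zip(temps, ksv))})"]
    for f in fits:
        rel = "exceeds" if f.kq > diffusion_limit else "does not exceed"
        evidence.append(
            f"Kq = {f.kq:.4g} L/mol/s at {f.temperature:.0f} K {rel} the "
            f"diffusion limit {diffusion_limit:.4g}"
        )
    if trend == "decreasing" and exceeds:
        verdict = "static"
        evidence.append(
            "decreasing Ksv with temperature and Kq above the diffusion limit: "
            "consistent with ground-state complex formation (static quenching)"
        )
    elif trend == "increasing" and not exceeds:
        verdict = "dynamic"
        evidence.append(
            "increasing Ksv with temperature and Kq within the diffusion limit: "
            "consistent with collisional (dynamic) quenching"
        )
    else:
        verdict = "ambiguous"
        evidence.append("evidence does not match either canonical pattern")
    return MechanismCall(
        verdict=verdict,
        ksv_trend=trend,
        kq_exceeds_diffusion_limit=exceeds,
        evidence=tuple(evidence),
    )
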