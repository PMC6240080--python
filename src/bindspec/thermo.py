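"""Van't Hoff regression, Gibbs free energy, and binding-force classification.

The van't Hoff regression fits ``log10(Kb) = -dH/(2.303*R*T) + dS/(2.303*R)``
as ordinary least squares of log10(Kb) on 1/T, giving the standard enthalpy
change ΔH° from the slope and entropy change ΔS° from the intercept.  Gibbs
free energy is available through two routes — ``ΔG° = ΔH° - T*ΔS°`` from the
regression, and ``ΔG° = -R*T*ln(Kb)`` directly from a binding constant — and
the two agree exactly whenever the Kb values are van't Hoff consistent.

Binding forces follow the usual sign rules: ΔH° < 0 and ΔS° < 0 point to
hydrogen bonding plus van der Waals contacts; both positive, hydrophobic
interactions; ΔH° < 0 with ΔS° > 0, electrostatic interactions.

R is fixed at 8.314 J mol⁻¹ K⁻¹ (not the fuller CODATA value) and the kcal
conversion uses the thermochemical calorie, 1 kcal = 4184 J.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, InvalidInputError

GAS_CONSTANT = 8.314  # J mol^-1 K^-1
J_PER_KCAL = 4184.0

FORCE_CLASSES = ("hbond_vdw", "hydrophobic", "electrostatic", "indeterminate")


@dataclass(frozen=True)
class ThermoParams:
    """Van't Hoff results: ΔH° (J/mol), ΔS° (J mol⁻¹ K⁻¹), ΔG°(T) (J/mol)."""

    dH: float
    dS: float
    dG_at: dict[float, float]
    r_squared: float
    force_class: str
    gas_constant: float = GAS_CONSTANT

    def __post_init__(self):
        if self.force_class not in FORCE_CLASSES:
            raise InvalidInputError(f"unknown force class {self.force_class!r}")


def classify_forces(dH: float, dS: float) -> str:
    """Dominant binding force from the signs of ΔH° and ΔS° (pure sign lookup)."""
    if dH < 0 and dS < 0:
        return "hbond_vdw"
    if dH > 0 and dS > 0:
        return "hydrophobic"
    if dH < 0 and dS > 0:
        return "electrostatic"
    return "indeterminate"


def gibbs_from_enthalpy_entropy(dH: float, dS: float, temperature: float) -> float:
    """ΔG° = ΔH° − T·ΔS° in J/mol."""
    if temperature <= 0:
        raise InvalidInputError("temperature must be > 0 K")
    return dH - temperature * dS


def gibbs_from_kb(kb: float, temperature: float) -> float:
    """ΔG° = −R·T·ln(Kb) in J/mol, the direct route from a binding constant."""
    if kb <= 0:
        raise InvalidInputError("Kb must be > 0")
    if temperature <= 0:
        raise InvalidInputError("temperature must be > 0 K")
    return -GAS_CONSTANT * temperature * math.log(kb)


def joules_to_kcal(value: float) -> float:
    """J/mol → kcal/mol (thermochemical calorie, 4184 J/kcal)."""
    return value / J_PER_KCAL


def kcal_to_joules(value: float) -> float:
    return value * J_PER_KCAL


def fit_vant_hoff(kb_by_T) -> ThermoParams:
    """OLS of log10(Kb) on 1/T; ΔH° = −2.303·R·slope, ΔS° = 2.303·R·intercept.

    ``kb_by_T`` is an iterable of ``(temperature K, Kb L/mol)`` pairs (order
    immaterial).  ΔG° is populated at each input temperature via ΔH° − T·ΔS°.
    """
    pairs = [(float(t), float(kb)) for t, kb in kb_by_T]
    if len(pairs) < 2:
        raise InsufficientDataError("van't Hoff fit needs >= 2 (T, Kb) points")
    temps = [t for t, _ in pairs]
    if len(set(temps)) != len(temps):
        raise InvalidInputError(f"duplicate temperatures: {temps}")
    if any(t <= 0 for t in temps):
        raise InvalidInputError("temperatures must be > 0 K")
    if any(kb <= 0 for _, kb in pairs):
        raise InvalidInputError("all Kb values must be > 0")
    x = np.array([1.0 / t for t, _ in pairs])
    y = np.array([math.log10(kb) for _, kb in pairs])
    if np.allclose(y, y[0]):
        # Kb independent of temperature: dH = 0, dS from the common level
        slope, intercept, r_squared = 0.0, float(y[0]), 1.0
    else:
        res = stats.linregress(x, y)
        slope, intercept = float(res.slope), float(res.intercept)
        r_squared = float(res.rvalue) ** 2
    dH = -2.303 * GAS_CONSTANT * slope
    dS = 2.303 * GAS_CONSTANT * intercept
    dG_at = {t: gibbs_from_enthalpy_entropy(dH, dS, t) for t in temps}
    return ThermoParams(
        dH=dH,
        dS=dS,
        dG_at=dG_at,
        r_squared=r_squared,
        force_class=classify_forces(dH, dS),
    )
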