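"""Core spectral containers and plain-text I/O.

A :class:`Spectrum` is one recorded trace — an ordered axis (nm for
emission/absorbance/CD, cm⁻¹ for IR) with a signal value at each point and a
kind tag.  A :class:`TitrationSeries` groups spectra of one protein solution
at a single temperature over increasing quencher concentrations; its first
point is always quencher-free and defines the reference intensity F₀.

Spectrum files are two-column delimited text (comma or whitespace separated)
with ``#`` comment lines.  Titration manifests are YAML files with the keys
``protein_conc_uM``, ``temperature_K``, ``excitation_nm``, ``kind`` and
``points`` (a list of ``{quencher_uM, file}`` entries, paths relative to the
manifest).  Concentrations are carried internally in mol/L.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import (
    IncompatibleGridError,
    InsufficientDataError,
    InvalidInputError,
    MissingReferenceError,
    OrderingError,
    OutOfRangeError,
    SpectrumParseError,
)

#: Recognised spectrum kinds and their axis units.
SPECTRUM_KINDS = {
    "emission": "nm",
    "absorbance": "nm",
    "cd_ellipticity_mdeg": "nm",
    "ir_absorbance": "cm-1",
}


@dataclass(frozen=True)
class Spectrum:
    """One recorded trace: strictly increasing axis, finite signal, kind tag."""

    axis: np.ndarray
    signal: np.ndarray
    kind: str

    def __post_init__(self):
        axis = np.asarray(self.axis, dtype=float)
        signal = np.asarray(self.signal, dtype=float)
        if self.kind not in SPECTRUM_KINDS:
            raise InvalidInputError(
                f"unknown spectrum kind {self.kind!r}; "
                f"expected one of {sorted(SPECTRUM_KINDS)}"
            )
        if axis.ndim != 1 or signal.ndim != 1 or axis.size != signal.size:
            raise InvalidInputError("axis and signal must be 1-D and equal length")
        if axis.size < 3:
            raise InsufficientDataError(
                f"spectrum needs at least 3 points, got {axis.size}"
            )
        if not np.all(np.isfinite(axis)) or not np.all(np.isfinite(signal)):
            raise InvalidInputError("axis and signal must be finite everywhere")
        # normalise to ascending axis order on construction
        order = np.argsort(axis, kind="stable")
        axis = axis[order]
        signal = signal[order]
        if np.any(np.diff(axis) == 0):
            raise InvalidInputError("duplicated axis values are not allowed")
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "signal", signal)
        self.axis.setflags(write=False)
        self.signal.setflags(write=False)

    @property
    def axis_unit(self) -> str:
        return SPECTRUM_KINDS[self.kind]

    def value_at(self, position: float) -> float:
        """Signal at an axis position, linearly interpolated between grid points.

        Exact grid hits return the stored value; positions outside the axis
        range raise :class:`OutOfRangeError`.
        """
        if position < self.axis[0] or position > self.axis[-1]:
            raise OutOfRangeError(
                f"position {position} outside axis range "
                f"[{self.axis[0]}, {self.axis[-1]}] {self.axis_unit}"
            )
        return float(np.interp(position, self.axis, self.signal))

    def peak_position(self) -> float:
        """Axis position of the global signal maximum."""
        return float(self.axis[int(np.argmax(self.signal))])


@dataclass(frozen=True)
class TitrationPoint:
    """One titration step: quencher concentration (mol/L) and its spectrum."""

    quencher_conc: float
    spectrum: Spectrum

    def __post_init__(self):
        if self.quencher_conc < 0:
            raise InvalidInputError(
                f"quencher concentration must be >= 0, got {self.quencher_conc}"
            )


@dataclass(frozen=True)
class TitrationSeries:
    """Spectra of one protein solution at one temperature, increasing quencher.

    The first point must be quencher-free (it defines F₀), concentrations must
    be strictly increasing, and all spectra must share kind and axis grid.
    """

    protein_conc: float
    temperature: float
    excitation_wavelength: float
    points: tuple[TitrationPoint, ...]

    def __post_init__(self):
        object.__setattr__(self, "points", tuple(self.points))
        if self.protein_conc <= 0:
            raise InvalidInputError("protein concentration must be > 0 mol/L")
        if self.temperature <= 0:
            raise InvalidInputError("temperature must be > 0 K")
        if len(self.points) < 3:
            raise InsufficientDataError(
                f"titration series needs >= 3 points, got {len(self.points)}"
            )
        concs = [p.quencher_conc for p in self.points]
        if concs[0] != 0:
            raise MissingReferenceError(
                f"first titration point must be quencher-free (defines F0); "
                f"got {concs[0]} mol/L"
            )
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise OrderingError(
                f"quencher concentrations must be strictly increasing, got {concs}"
            )
        kinds = {p.spectrum.kind for p in self.points}
        if len(kinds) != 1:
            raise InvalidInputError(f"mixed spectrum kinds in one series: {kinds}")
        ref_axis = self.points[0].spectrum.axis
        for p in self.points[1:]:
            if not np.array_equal(p.spectrum.axis, ref_axis):
                raise IncompatibleGridError(
                    "all spectra in a titration series must share one axis grid"
                )

    @property
    def kind(self) -> str:
        return self.points[0].spectrum.kind

    @property
    def quencher_concs(self) -> np.ndarray:
        return np.array([p.quencher_conc for p in self.points])

    def reference_spectrum(self) -> Spectrum:
        """The quencher-free spectrum (first point)."""
        return self.points[0].spectrum


def read_spectrum(path: str | os.PathLike, kind: str) -> Spectrum:
    """Read a two-column delimited text spectrum.

    Accepts comma- or whitespace-separated columns and ``#`` comments.  The
    axis is sorted ascending on load; duplicated axis values are rejected.
    Malformed rows raise :class:`SpectrumParseError` naming the line number.
    """
    axis: list[float] = []
    signal: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise SpectrumParseError(
                    f"expected two columns, got {len(parts)} in {path!s}", lineno
                )
            try:
                x, y = float(parts[0]), float(parts[1])
            except ValueError:
                raise SpectrumParseError(
                    f"non-numeric value {parts!r} in {path!s}", lineno
                ) from None
            axis.append(x)
            signal.append(y)
    if len(axis) < 3:
        raise InsufficientDataError(
            f"{path!s}: spectrum needs at least 3 points, got {len(axis)}"
        )
    return Spectrum(np.array(axis), np.array(signal), kind)


def write_spectrum(spectrum: Spectrum, path: str | os.PathLike) -> None:
    """Write a spectrum as two-column text at full float precision."""
    with open(path, "w") as fh:
        fh.write(f"# kind: {spectrum.kind}  axis_unit: {spectrum.axis_unit}\n")
        for x, y in zip(spectrum.axis, spectrum.signal):
            fh.write(f"{float(x)!r} {float(y)!r}\n")


def read_titration_manifest(
    path: str | os.PathLike, kind: str | None = None
) -> TitrationSeries:
    """Read a YAML titration manifest and its referenced spectrum files.

    Manifest schema::

        protein_conc_uM: 15.0
        temperature_K: 298.0
        excitation_nm: 280.0
        kind: emission            # optional, default emission
        points:
          - {quencher_uM: 0.0,  file: t298_q000.txt}
          - {quencher_uM: 15.0, file: t298_q015.txt}
          ...

    Spectrum paths are resolved relative to the manifest's directory.
    Micromolar concentrations are converted to mol/L on load.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise InvalidInputError(f"{path!s}: manifest must be a YAML mapping")
    for key in ("protein_conc_uM", "temperature_K", "excitation_nm", "points"):
        if key not in doc:
            raise InvalidInputError(f"{path!s}: manifest missing key {key!r}")
    spec_kind = kind or doc.get("kind", "emission")
    base = os.path.dirname(os.fspath(path))
    points = []
    for entry in doc["points"]:
        if "quencher_uM" not in entry or "file" not in entry:
            raise InvalidInputError(
                f"{path!s}: each point needs 'quencher_uM' and 'file', got {entry}"
            )
        spec_path = os.path.join(base, entry["file"])
        spectrum = read_spectrum(spec_path, spec_kind)
        points.append(
            TitrationPoint(quencher_conc=float(entry["quencher_uM"]) * 1e-6,
                           spectrum=spectrum)
        )
    return TitrationSeries(
        protein_conc=float(doc["protein_conc_uM"]) * 1e-6,
        temperature=float(doc["temperature_K"]),
        excitation_wavelength=float(doc["excitation_nm"]),
        points=tuple(points),
    )


def write_titration_manifest(
    series: TitrationSeries, directory: str | os.PathLike, stem: str
) -> str:
    """Write a series as spectrum files plus a YAML manifest; returns its path."""
    os.makedirs(directory, exist_ok=True)
    entries = []
    for i, point in enumerate(series.points):
        fname = f"{stem}_q{i:02d}.txt"
        write_spectrum(point.spectrum, os.path.join(directory, fname))
        entries.append(
            {"quencher_uM": float(point.quencher_conc) * 1e6, "file": fname}
        )
    doc = {
        "protein_conc_uM": float(series.protein_conc) * 1e6,
        "temperature_K": float(series.temperature),
        "excitation_nm": float(series.excitation_wavelength),
        "kind": series.kind,
        "points": entries,
    }
    manifest_path = os.path.join(directory, f"{stem}.yaml")
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return manifest_path


def extract_intensity(
    series: TitrationSeries, wavelength: float
) -> tuple[np.ndarray, np.ndarray]:
    """Signal at one axis position across a titration.

    Returns ``(quencher_concs, intensities)`` with the intensity read at
    ``wavelength`` from every spectrum by linear interpolation (exact on grid
    hits).  This is the single-wavelength reading used for all quenching fits:
    the analysis wavelength defaults elsewhere to the emission maximum of the
    quencher-free spectrum.
    """
    concs = series.quencher_concs
    values = np.array([p.spectrum.value_at(wavelength) for p in series.points])
    return concs, values
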