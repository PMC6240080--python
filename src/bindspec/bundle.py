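"""Self-contained synthetic study bundles.

:func:`write_fixture_bundle` emits, under one directory, everything a full
analysis run consumes — emission titration manifests at three temperatures,
a UV absorbance titration, a CD titration with drifting structure fractions,
free/bound amide-band IR spectra, the basis file, an analysis config — plus
``truth.yaml`` recording every generative parameter, so end-to-end runs can
be scored by parameter recovery.  All spectra are synthetic; the default
conditions emulate a serum-albumin/ligand study (15 μM protein, quencher
0–120 μM, temperatures 288/298/308 K, exothermic binding with negative
entropy, helix-to-random CD drift, amide I and II peak shifts).
"""

from __future__ import annotations

import os

import yaml

from .simulate import (
    DEFAULT_QUENCHER_CONCS,
    DEFAULT_TEMPERATURES,
    ThermoGroundTruth,
    canonical_cd_basis,
    quenching_truth_from_thermo,
    simulate_band_spectrum,
    simulate_cd_spectrum,
    simulate_quenching_titration,
    simulate_uv_titration,
)
from .spectra import Spectrum, write_spectrum, write_titration_manifest

#: CD structure-fraction drift across molar ratios 1:0 … 1:8
#: (alpha_helix, beta, turn, random); helix falls as random grows.
CD_FRACTION_DRIFT = (
    (0.368, 0.0, 0.268, 0.364),
    (0.286, 0.0, 0.206, 0.508),
    (0.164, 0.0, 0.385, 0.451),
    (0.149, 0.0, 0.392, 0.459),
    (0.148, 0.0, 0.385, 0.467),
    (0.142, 0.0, 0.381, 0.477),
    (0.138, 0.0, 0.363, 0.499),
    (0.150, 0.0, 0.356, 0.494),
    (0.133, 0.0, 0.342, 0.525),
)

#: Amide-band centres (cm⁻¹) for the free and bound IR spectra.
IR_CENTERS_FREE = {"amide_I": 1640.63, "amide_II": 1535.60}
IR_CENTERS_BOUND = {"amide_I": 1647.59, "amide_II": 1539.50}
IR_WIDTH = 10.0  # half width at half maximum, cm^-1; keeps the two bands resolved


def _ir_spectrum(centers: dict[str, float], axis) -> Spectrum:
    sig = None
    for center in centers.values():
        band = simulate_band_spectrum(center, IR_WIDTH, 1.0, axis,
                                      noise_sd=0.0, kind="ir_absorbance")
        sig = band.signal if sig is None else sig + band.signal
    return Spectrum(axis, sig, "ir_absorbance")


def write_fixture_bundle(
    directory: str | os.PathLike,
    seed: int = 0,
    dH: float = -128470.0,
    dS: float = -359.49,
    n: float = 1.0,
    noise_sd: float = 0.0,
    temperatures=DEFAULT_TEMPERATURES,
) -> str:
    """Write a complete synthetic study bundle; returns the config path.

    Binding constants at each temperature follow the van't Hoff relation for
    (``dH``, ``dS``); quenching titrations obey ``F = F0/(1 + Kb*Q**n)`` with
    optional Gaussian noise (sd as a fraction of F0).
    """
    import numpy as np

    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    thermo_truth = ThermoGroundTruth(dH=dH, dS=dS,
                                     temperatures=tuple(temperatures))
    truth = quenching_truth_from_thermo(thermo_truth, n=n,
                                        noise_sd=noise_sd, seed=seed)

    manifests = []
    for T in thermo_truth.temperatures:
        series = simulate_quenching_titration(truth, T)
        path = write_titration_manifest(series, directory, f"emission_{int(T)}K")
        manifests.append(os.path.basename(path))

    uv = simulate_uv_titration()
    uv_manifest = os.path.basename(
        write_titration_manifest(uv, directory, "uv_absorbance")
    )

    basis = canonical_cd_basis()
    basis.write(os.path.join(directory, "cd_basis.txt"))
    cd_entries = []
    for i, fractions in enumerate(CD_FRACTION_DRIFT):
        spec = simulate_cd_spectrum(fractions, basis, noise_sd=noise_sd,
                                    seed=seed + i)
        fname = f"cd_ratio_1to{i}.txt"
        write_spectrum(spec, os.path.join(directory, fname))
        cd_entries.append({"label": f"1:{i}", "file": fname})

    ir_axis = np.arange(1450.0, 1750.5, 0.5)
    write_spectrum(_ir_spectrum(IR_CENTERS_FREE, ir_axis),
                   os.path.join(directory, "ir_free.txt"))
    write_spectrum(_ir_spectrum(IR_CENTERS_BOUND, ir_axis),
                   os.path.join(directory, "ir_bound.txt"))

    config = {
        "titrations": manifests,
        "uv_titration": uv_manifest,
        "cd": {"basis": "cd_basis.txt", "spectra": cd_entries},
        "ir": {"free": "ir_free.txt", "bound": "ir_bound.txt"},
        "seed": seed,
        "output_dir": "report",
    }
    config_path = os.path.join(directory, "config.yaml")
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)

    truth_doc = {
        "seed": seed,
        "dH_J_per_mol": dH,
        "dS_J_per_mol_K": dS,
        "n_sites": n,
        "noise_sd": noise_sd,
        "kb_per_T": {float(T): float(kb) for T, kb in truth.kb_per_T.items()},
        "cd_fractions": [list(f) for f in CD_FRACTION_DRIFT],
        "ir_centers_free": IR_CENTERS_FREE,
        "ir_centers_bound": IR_CENTERS_BOUND,
    }
    with open(os.path.join(directory, "truth.yaml"), "w") as fh:
        yaml.safe_dump(truth_doc, fh, sort_keys=False)
    return config_path
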