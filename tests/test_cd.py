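"""Molar ellipticity and simplex-constrained CD structure unmixing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bindspec import (
    BasisSet,
    Spectrum,
    estimate_secondary_structure,
    simulate_cd_spectrum,
    to_molar_ellipticity,
    track_titration_structure,
)
from bindspec.cd import STRUCTURE_NAMES, _solve_simplex
from bindspec.errors import IncompatibleGridError, InvalidInputError

FREE_PROTEIN_FRACTIONS = (0.368, 0.0, 0.268, 0.364)


class TestMolarEllipticity:
    def test_zero_signal(self):
        assert to_molar_ellipticity(0.0, 15e-6, 0.1) == 0.0

    def test_scale_cancellation(self):
        assert to_molar_ellipticity(-7.5, 100.0, 1.0) == pytest.approx(-7.5)

    def test_direct_evaluation(self):
        expected = 100.0 * (-5.0) / (15e-6 * 0.1)
        assert to_molar_ellipticity(-5.0, 15e-6, 0.1) == pytest.approx(expected)

    def test_pointwise_over_arrays(self):
        theta = np.array([-5.0, 0.0, 2.0])
        out = to_molar_ellipticity(theta, 15e-6, 0.1)
        assert np.allclose(out, 100.0 * theta / (15e-6 * 0.1))

    @pytest.mark.parametrize("conc, path", [(0.0, 0.1), (-1e-6, 0.1),
                                            (15e-6, 0.0), (15e-6, -1.0)])
    def test_invalid_geometry_rejected(self, conc, path):
        with pytest.raises(InvalidInputError):
            to_molar_ellipticity(1.0, conc, path)


class TestUnmixing:
    @pytest.mark.parametrize("vertex", range(4))
    def test_vertex_recovery(self, basis, vertex):
        frac = [0.0] * 4
        frac[vertex] = 1.0
        spec = simulate_cd_spectrum(frac, basis)
        fit = estimate_secondary_structure(spec, basis)
        assert np.allclose(fit.as_array(), frac, atol=1e-8)
        assert fit.residual_rms == pytest.approx(0.0, abs=1e-8)

    def test_interior_recovery_to_1e6(self, basis):
        spec = simulate_cd_spectrum(FREE_PROTEIN_FRACTIONS, basis)
        fit = estimate_secondary_structure(spec, basis)
        assert np.allclose(fit.as_array(), FREE_PROTEIN_FRACTIONS, atol=1e-6)

    def test_noisy_recovery_is_unbiased(self, basis):
        """Mean recovered helix over 100 seeds at 0.5 mdeg noise stays within
        0.02 of the generating value."""
        helices = []
        for seed in range(100):
            spec = simulate_cd_spectrum(FREE_PROTEIN_FRACTIONS, basis,
                                        noise_sd=0.5, seed=seed)
            helices.append(estimate_secondary_structure(spec, basis).alpha_helix)
        assert abs(np.mean(helices) - FREE_PROTEIN_FRACTIONS[0]) < 0.02

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        raw=st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4),
        noise=st.floats(0.0, 5.0),
    )
    def test_simplex_constraints_hold_under_noise(self, basis, raw, noise):
        """Fractions stay in [0,1] and sum to 1 no matter the noise level."""
        frac = np.array(raw) / np.sum(raw)
        frac = frac / frac.sum()
        spec = simulate_cd_spectrum(frac / frac.sum(), basis,
                                    noise_sd=noise, seed=1)
        fit = estimate_secondary_structure(spec, basis)
        arr = fit.as_array()
        assert np.all(arr >= 0) and np.all(arr <= 1)
        assert arr.sum() == pytest.approx(1.0, abs=1e-6)

    def test_scale_equivariance(self, basis):
        spec = simulate_cd_spectrum(FREE_PROTEIN_FRACTIONS, basis,
                                    noise_sd=1.0, seed=2)
        scaled_basis = BasisSet(
            axis=basis.axis,
            components={k: 7.5 * v for k, v in basis.components.items()},
        )
        scaled_spec = Spectrum(spec.axis, 7.5 * spec.signal,
                               "cd_ellipticity_mdeg")
        a = estimate_secondary_structure(spec, basis)
        b = estimate_secondary_structure(scaled_spec, scaled_basis)
        assert np.allclose(a.as_array(), b.as_array(), atol=1e-9)

    def test_residual_never_grows_with_more_components(self, basis):
        """Optimal simplex residual with all four components is no larger
        than with any three of them."""
        spec = simulate_cd_spectrum((0.4, 0.2, 0.2, 0.2), basis,
                                    noise_sd=2.0, seed=3)
        A_full = np.column_stack(
            [basis.components[n] for n in STRUCTURE_NAMES]
        )
        _, full_resid = _solve_simplex(A_full, spec.signal)
        for drop in range(4):
            cols = [i for i in range(4) if i != drop]
            _, sub_resid = _solve_simplex(A_full[:, cols], spec.signal)
            assert full_resid <= sub_resid + 1e-9

    def test_no_axis_overlap_rejected(self, basis):
        axis = np.arange(300.0, 341.0, 1.0)
        spec = Spectrum(axis, np.zeros(axis.size), "cd_ellipticity_mdeg")
        with pytest.raises(IncompatibleGridError):
            estimate_secondary_structure(spec, basis)

    def test_too_few_shared_points_rejected(self, basis):
        spec = simulate_cd_spectrum(FREE_PROTEIN_FRACTIONS, basis)
        with pytest.raises(IncompatibleGridError):
            estimate_secondary_structure(spec, basis, window=(200.0, 210.0))


class TestTitrationTracking:
    def test_single_spectrum_degenerate_list(self, basis):
        spec = simulate_cd_spectrum(FREE_PROTEIN_FRACTIONS, basis)
        rows, trend = track_titration_structure([("free", spec)], basis)
        assert len(rows) == 1
        direct = estimate_secondary_structure(spec, basis)
        assert np.allclose(rows[0][1].as_array(), direct.as_array())

    def test_helix_loss_reported_as_decreasing(self, basis):
        from bindspec.bundle import CD_FRACTION_DRIFT

        labelled = [
            (f"1:{i}", simulate_cd_spectrum(frac, basis))
            for i, frac in enumerate(CD_FRACTION_DRIFT)
        ]
        rows, trend = track_titration_structure(labelled, basis)
        assert trend == "decreasing"
        assert rows[0][1].alpha_helix == pytest.approx(0.368, abs=1e-6)
        assert rows[-1][1].alpha_helix == pytest.approx(0.133, abs=1e-6)

    def test_empty_list_rejected(self, basis):
        with pytest.raises(InvalidInputError):
            track_titration_structure([], basis)
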