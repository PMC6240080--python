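"""Stern–Volmer and binding fits, inner-filter correction, mechanism call."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bindspec import (
    QuenchingFit,
    QuenchingGroundTruth,
    classify_mechanism,
    correct_inner_filter,
    fit_binding,
    fit_stern_volmer,
    simulate_quenching_titration,
)
from bindspec.errors import (
    DegenerateSignalError,
    InsufficientDataError,
    InvalidInputError,
)

Q_GRID = tuple(np.arange(0.0, 121.0, 15.0) * 1e-6)


def _series(kb, n=1.0, noise_sd=0.0, seed=0, temperature=298.0):
    truth = QuenchingGroundTruth(kb_per_T={temperature: kb}, n=n,
                                 noise_sd=noise_sd, seed=seed)
    return simulate_quenching_titration(truth, temperature)


def _fit(ksv, temperature, tau0=1e-8):
    return QuenchingFit(ksv=ksv, ksv_se=0.0, intercept=1.0, r_squared=1.0,
                        tau0=tau0, temperature=temperature)


class TestInnerFilter:
    def test_zero_absorbance_identity(self):
        assert correct_inner_filter(100.0, 0.0, 0.0) == 100.0

    def test_zero_signal(self):
        assert correct_inner_filter(0.0, 0.3, 0.7) == 0.0

    def test_exponential_value(self):
        # 100*e^0.1; reference value from 30-digit sympy evaluation of exp(1/10)
        assert correct_inner_filter(100.0, 0.1, 0.1) == pytest.approx(
            110.5170918075648, rel=1e-12
        )

    def test_negative_absorbance_rejected(self):
        with pytest.raises(InvalidInputError):
            correct_inner_filter(10.0, -0.1, 0.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(f=st.floats(0, 1e6), a_ex=st.floats(0, 3), a_em=st.floats(0, 3))
    def test_correction_is_monotone_amplifying(self, f, a_ex, a_em):
        """Corrected intensity >= observed, equal only at zero absorbance."""
        corrected = correct_inner_filter(f, a_ex, a_em)
        assert corrected >= f
        if f > 0 and (a_ex > 0 or a_em > 0):
            assert corrected > f


class TestSternVolmer:
    def test_noiseless_recovery_table_magnitude(self):
        """A 1:1 noiseless titration returns Ksv = Kb with a unit intercept."""
        fit = fit_stern_volmer(_series(10531.0), wavelength=344.0)
        assert fit.ksv == pytest.approx(10531.0, rel=1e-9)
        assert fit.intercept == pytest.approx(1.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.warnings == ()

    def test_constant_signal_means_no_quenching(self, noiseless_series):
        series = noiseless_series(kb=5200.0)
        concs = series.quencher_concs
        flat = (concs, np.full(concs.size, 800.0))
        fit = fit_stern_volmer(flat)
        assert fit.ksv == 0.0
        assert fit.intercept == 1.0

    def test_kq_from_tau0(self):
        fit = fit_stern_volmer(_series(10531.0), tau0=1e-8, wavelength=344.0)
        assert fit.kq == pytest.approx(1.0531e12, rel=1e-9)

    def test_kq_scales_inversely_with_tau0(self):
        series = _series(5200.0)
        a = fit_stern_volmer(series, tau0=1e-8, wavelength=344.0)
        b = fit_stern_volmer(series, tau0=2e-8, wavelength=344.0)
        assert b.kq == pytest.approx(a.kq / 2.0, rel=1e-12)

    def test_default_wavelength_is_f0_peak(self):
        series = _series(5200.0)
        assert fit_stern_volmer(series).ksv == pytest.approx(
            fit_stern_volmer(series, wavelength=344.0).ksv
        )

    def test_nonpositive_signal_rejected(self):
        concs = np.array([0.0, 1e-5, 2e-5])
        with pytest.raises(DegenerateSignalError):
            fit_stern_volmer((concs, np.array([100.0, 50.0, 0.0])))

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_stern_volmer((np.array([0.0, 1e-5]), np.array([100.0, 50.0])))

    def test_intercept_deviation_warning(self):
        concs = np.array([0.0, 1e-5, 2e-5, 3e-5])
        f = np.array([100.0, 95.0, 50.0, 33.0])  # strongly non-linear ratio
        fit = fit_stern_volmer((concs, f))
        assert abs(fit.intercept - 1) > 0.05
        assert any("intercept" in w for w in fit.warnings)

    def test_noisy_ksv_within_three_se(self):
        """Over 200 seeded replicates at 2% noise, |Ksv - truth| <= 3 SE
        in at least 95% of fits."""
        hits = 0
        for seed in range(200):
            fit = fit_stern_volmer(
                _series(5200.0, noise_sd=0.02, seed=seed), wavelength=344.0
            )
            if abs(fit.ksv - 5200.0) <= 3.0 * fit.ksv_se:
                hits += 1
        assert hits >= 190


class TestBindingFit:
    @pytest.mark.parametrize("kb", [1e2, 1e3, 1e4, 1e5])
    @pytest.mark.parametrize("n", [0.8, 0.97, 1.0, 1.2])
    def test_noiseless_parameter_recovery(self, kb, n):
        fit = fit_binding(_series(kb, n=n), wavelength=344.0)
        assert fit.kb == pytest.approx(kb, rel=1e-3)
        assert fit.n == pytest.approx(n, abs=1e-3)
        assert fit.points_excluded == 1  # the Q=0 reference point

    def test_matches_stern_volmer_at_unit_stoichiometry(self):
        series = _series(5200.0, n=1.0)
        sv = fit_stern_volmer(series, wavelength=344.0)
        bind = fit_binding(series, wavelength=344.0)
        assert bind.kb == pytest.approx(sv.ksv, rel=1e-3)

    def test_unquenched_series_rejected(self, noiseless_series):
        series = noiseless_series(kb=5200.0)
        concs = series.quencher_concs
        with pytest.raises(InsufficientDataError):
            fit_binding((concs, np.full(concs.size, 1000.0)))


class TestMechanismClassification:
    def test_static_pattern(self):
        """Decreasing Ksv with every Kq above the diffusion limit -> static."""
        fits = [_fit(1.0531e4, 288.0), _fit(0.7803e4, 298.0),
                _fit(0.7455e4, 308.0)]
        call = classify_mechanism(fits)
        assert call.verdict == "static"
        assert call.ksv_trend == "decreasing"
        assert call.kq_exceeds_diffusion_limit
        assert len(call.evidence) >= 4

    def test_dynamic_pattern(self):
        fits = [_fit(1e2, 288.0), _fit(2e2, 298.0), _fit(3e2, 308.0)]
        call = classify_mechanism(fits)
        assert call.verdict == "dynamic"
        assert call.ksv_trend == "increasing"
        assert not call.kq_exceeds_diffusion_limit

    @pytest.mark.parametrize(
        "ksvs, trend",
        [
            ((1e4, 2e4, 1.5e4), "non-monotonic"),
            ((1e4, 1e4, 2e4), "non-monotonic"),  # tie counts as non-monotonic
        ],
    )
    def test_non_monotonic_is_ambiguous(self, ksvs, trend):
        fits = [_fit(k, T) for k, T in zip(ksvs, (288.0, 298.0, 308.0))]
        call = classify_mechanism(fits)
        assert call.verdict == "ambiguous"
        assert call.ksv_trend == trend

    def test_mixed_evidence_is_ambiguous(self):
        # decreasing trend but Kq below the limit
        low = [_fit(3e2, 288.0), _fit(2e2, 298.0), _fit(1e2, 308.0)]
        assert classify_mechanism(low).verdict == "ambiguous"
        # increasing trend but Kq above the limit
        high = [_fit(1e4, 288.0), _fit(2e4, 298.0), _fit(3e4, 308.0)]
        assert classify_mechanism(high).verdict == "ambiguous"

    def test_duplicate_temperatures_rejected(self):
        with pytest.raises(InvalidInputError):
            classify_mechanism([_fit(1e4, 298.0), _fit(2e4, 298.0)])

    def test_input_order_irrelevant(self):
        fits = [_fit(0.7455e4, 308.0), _fit(1.0531e4, 288.0),
                _fit(0.7803e4, 298.0)]
        assert classify_mechanism(fits).verdict == "static"
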