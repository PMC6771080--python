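"""Nanoparticle heating: relaxation times, susceptibility, SLP and power fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mfhplan.constants import KB, MU0
from mfhplan.mnp import (
    POWER_TABLE,
    FerrofluidDose,
    FieldExposure,
    InvalidParameterError,
    MNPSuite,
    anisotropy_field,
    brown_time,
    chi_imag,
    effective_time,
    fit_power_line,
    neel_time,
    slp,
    suite_with,
    volumetric_power,
    _size_grid,
    _slp_integrand,
)


class TestAnisotropyField:
    def test_characterised_suite(self, suite):
        assert anisotropy_field(suite) == pytest.approx(92.0e3, rel=1e-12)

    def test_inverse_in_ms(self, suite):
        halved = suite_with(suite, Ms=suite.Ms / 2.0)
        assert anisotropy_field(halved) == pytest.approx(184.0e3, rel=1e-12)

    def test_vanishes_for_large_ms(self, suite):
        huge = suite_with(suite, Ms=1e15)
        assert anisotropy_field(huge) < 1e-3

    def test_nonpositive_ms_rejected(self, suite):
        with pytest.raises(InvalidParameterError):
            suite_with(suite, Ms=-1.0)


class TestNeelTime:
    def test_zero_field_closed_form(self, suite):
        """At h=0 the two-well rate collapses to exp(sigma)/(2 f0)."""
        V = suite.magnetic_volume(suite.d_median)
        sigma = suite.K * V / (KB * suite.T)
        expected = math.exp(sigma) / (2.0 * suite.f0)
        tau = neel_time(suite, FieldExposure(0.0, 171e3), V)
        assert tau == pytest.approx(expected, rel=1e-12)
        assert tau == pytest.approx(3.35e-4, rel=0.01)

    def test_small_barrier_limit(self, suite):
        tiny = suite_with(suite, K=1e-6)
        V = suite.magnetic_volume(suite.d_median)
        assert neel_time(tiny, FieldExposure(0.0, 171e3), V) == pytest.approx(
            1.0 / (2.0 * suite.f0), rel=1e-9
        )

    def test_strictly_decreasing_in_reduced_field(self, suite):
        """tau_N(h) falls monotonically as the applied field tilts the barrier.

        The monotone range is [0, ~0.75]: very close to h = 1 the (1-h^2)
        attempt-rate prefactor vanishes and the escape time turns back up
        (the barrier picture itself degrades there)."""
        V = suite.magnetic_volume(suite.d_median)
        Hk = anisotropy_field(suite)
        hs = np.linspace(0.0, 0.7, 40)
        taus = [neel_time(suite, FieldExposure(h * Hk, 171e3), V) for h in hs]
        assert np.all(np.diff(taus) < 0)
        # and the barrier is always lower than at zero field
        for h in (0.112, 0.5, 0.9):
            assert neel_time(suite, FieldExposure(h * Hk, 171e3), V) < taus[0]

    def test_field_beyond_anisotropy_rejected(self, suite):
        V = suite.magnetic_volume(suite.d_median)
        with pytest.raises(InvalidParameterError, match="anisotropy"):
            neel_time(suite, FieldExposure(93.0e3, 171e3), V)


class TestBrownTime:
    def test_zero_field_rotational_diffusion(self, suite):
        VH = suite.hydrodynamic_volume(suite.d_median)
        expected = 3.0 * suite.eta * VH / (KB * suite.T)
        tau = brown_time(suite, FieldExposure(0.0, 171e3), suite.magnetic_volume(suite.d_median), VH)
        assert tau == pytest.approx(expected, rel=1e-12)
        assert tau == pytest.approx(2.42e-6, rel=0.01)

    def test_field_correction(self, suite, exposure):
        VM = suite.magnetic_volume(suite.d_median)
        VH = suite.hydrodynamic_volume(suite.d_median)
        xi = MU0 * suite.Ms * VM * exposure.Hmax / (KB * suite.T)
        assert xi == pytest.approx(3.0, abs=0.01)
        assert brown_time(suite, exposure, VM, VH) == pytest.approx(1.89e-6, rel=0.01)

    @given(hmax=st.floats(0.0, 1e5), d=st.floats(5e-9, 40e-9))
    @settings(max_examples=50, deadline=None)
    def test_never_exceeds_zero_field_time(self, suite, hmax, d):
        VM = suite.magnetic_volume(d)
        VH = suite.hydrodynamic_volume(d)
        tau = brown_time(suite, FieldExposure(hmax, 171e3), VM, VH)
        tau0 = brown_time(suite, FieldExposure(0.0, 171e3), VM, VH)
        assert tau <= tau0 * (1 + 1e-12)

    def test_bad_volumes_rejected(self, suite, exposure):
        with pytest.raises(InvalidParameterError):
            brown_time(suite, exposure, -1.0, 1.0)
        with pytest.raises(InvalidParameterError):
            brown_time(suite, exposure, 2e-24, 1e-24)


class TestEffectiveTime:
    def test_symmetric_harmonic(self):
        assert effective_time(2.0, 2.0, "mobilised") == pytest.approx(1.0)

    def test_dominated_by_faster_channel(self):
        tau = effective_time(3.35e-4, 1.89e-6, "mobilised")
        assert tau == pytest.approx(1.88e-6, rel=0.01)
        assert tau <= min(3.35e-4, 1.89e-6)

    def test_immobilised_keeps_neel_only(self):
        assert effective_time(3.35e-4, 1.89e-6, "immobilised") == 3.35e-4

    @given(tn=st.floats(1e-9, 1e-2), tb=st.floats(1e-9, 1e-2))
    @settings(max_examples=50, deadline=None)
    def test_bounded_by_both_channels(self, tn, tb):
        tau = effective_time(tn, tb, "mobilised")
        assert tau <= min(tn, tb) * (1 + 1e-12)


class TestChiImag:
    def test_debye_peak(self, suite, exposure):
        """chi'' peaks at 2*pi*f*tau = 1 with value chi0/2."""
        VM = suite.magnetic_volume(suite.d_median)
        tau_peak = 1.0 / exposure.omega
        chi0 = MU0 * suite.Ms**2 * VM / (3.0 * KB * suite.T)
        assert chi_imag(suite, exposure, tau_peak, VM) == pytest.approx(chi0 / 2.0, rel=1e-12)
        # neighbourhood is lower
        for fac in (0.5, 2.0):
            assert chi_imag(suite, exposure, fac * tau_peak, VM) < chi0 / 2.0

    def test_limits(self, suite, exposure):
        VM = suite.magnetic_volume(suite.d_median)
        assert chi_imag(suite, exposure, 1e-15, VM) < 1e-6
        assert chi_imag(suite, exposure, 1e3, VM) < 1e-6

    def test_debye_factor_value(self, suite):
        VM = suite.magnetic_volume(suite.d_median)
        exp = FieldExposure(10.3e3, 171e3)
        x = exp.omega * 1.88e-6
        chi0 = MU0 * suite.Ms**2 * VM / (3.0 * KB * suite.T)
        ratio = chi_imag(suite, exp, 1.88e-6, VM) / chi0
        assert ratio == pytest.approx(x / (1 + x * x), rel=1e-12)
        assert ratio == pytest.approx(0.399, abs=0.002)


class TestSLP:
    def test_zero_field_gives_zero(self, suite):
        assert slp(suite, FieldExposure(0.0, 171e3)) == 0.0

    def test_monodisperse_limit(self, suite, exposure):
        mono = suite_with(suite, s_ln=1e-9)
        val = slp(mono, exposure, "mobilised")
        single = _slp_integrand(mono, exposure, "mobilised", np.array([suite.d_median]))[0]
        assert val == pytest.approx(single, rel=1e-12)

    @pytest.mark.parametrize("mode", ["mobilised", "immobilised"])
    def test_matches_fine_grid_oracle(self, suite, exposure, mode):
        """Adaptive quadrature agrees with a brute-force fine trapezoid sum."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            s = suite_with(
                suite,
                d_median=rng.uniform(10e-9, 20e-9),
                s_ln=rng.uniform(0.05, 0.3),
                K=rng.uniform(15e3, 35e3),
                eta=rng.uniform(5e-4, 5e-3),
            )
            val = slp(s, exposure, mode)
            d, w = _size_grid(s, n=5120)
            oracle = float(np.sum(w * _slp_integrand(s, exposure, mode, d)))
            assert val == pytest.approx(oracle, rel=1e-3)

    def test_brownian_channel_never_hurts_above_resonance(self, suite, exposure):
        """For suites whose Neel times sit above the Debye resonance (the
        regime of thermoseed-sized particles), adding the Brownian channel
        moves the effective time towards resonance and can only raise the
        loss.  (Below resonance -- very small cores -- extra mobility shortens
        tau away from the peak and the ordering genuinely reverses.)"""
        rng = np.random.default_rng(11)
        for _ in range(10):
            s = suite_with(
                suite,
                d_median=rng.uniform(14e-9, 25e-9),
                s_ln=rng.uniform(0.05, 0.25),
                eta=rng.uniform(5e-4, 1e-2),
            )
            assert slp(s, exposure, "mobilised") >= slp(s, exposure, "immobilised")

    def test_positive(self, suite, exposure):
        assert slp(suite, exposure, "immobilised") > 0


class TestVolumetricPower:
    def test_linear_in_concentration(self, suite, exposure):
        s = slp(suite, exposure)
        p1 = volumetric_power(s, FerrofluidDose(c_ref=5.0, phi_r=1.0))
        p_half = volumetric_power(s, FerrofluidDose(c_ref=5.0, phi_r=0.5))
        assert p_half == 0.5 * p1  # exact: pure multiplication
        assert volumetric_power(s, FerrofluidDose(c_ref=5.0, phi_r=0.0)) == 0.0

    def test_reference_table_scaling(self):
        """Relative powers in the reference table follow the linear dose law."""
        p1 = 243.0
        assert 0.5 * p1 == pytest.approx(121.0, abs=0.5)
        assert 0.35 * p1 == pytest.approx(84.2, abs=1.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(InvalidParameterError):
            FerrofluidDose(c_ref=5.0, phi_r=-0.1)


class TestFitPowerLine:
    def test_exact_line_recovered(self):
        pts = [(x, 2.0 * x + 1.0) for x in (0.1, 0.4, 0.9, 1.3)]
        slope, intercept = fit_power_line(pts)
        assert slope == pytest.approx(2.0, abs=1e-12)
        assert intercept == pytest.approx(1.0, abs=1e-12)

    def test_reference_table_fits(self):
        mob = fit_power_line(list(zip(POWER_TABLE["phi_r"], POWER_TABLE["mobilised"])))
        imm = fit_power_line(list(zip(POWER_TABLE["phi_r"], POWER_TABLE["immobilised"])))
        assert mob[0] == pytest.approx(244.4, abs=0.5)
        assert mob[1] == pytest.approx(-0.7826, abs=0.05)
        assert imm[0] == pytest.approx(170.3, abs=0.5)
        assert imm[1] == pytest.approx(-0.2539, abs=0.05)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(InvalidParameterError):
            fit_power_line([(1.0, 2.0)])
        with pytest.raises(InvalidParameterError, match="singular"):
            fit_power_line([(1.0, 2.0), (1.0, 3.0)])
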