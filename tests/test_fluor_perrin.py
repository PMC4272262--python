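"""Polarization arithmetic, Perrin fits, lifetime fits, viscosity table."""

import math

import numpy as np
import pytest

from g4shape.fluor_perrin import (PolarizationSeries,
                                  UndefinedPolarizationError,
                                  correlation_time, grating_factor,
                                  lifetime_fit, perrin_fit,
                                  phase_modulation, polarization,
                                  sucrose_viscosity)
from g4shape.synthdata import gen_lifetime, gen_perrin


class TestPolarization:
    def test_isotropic_emission(self):
        assert polarization(1.0, 1.0, G=1.0) == 0.0

    def test_printed_definition(self):
        assert polarization(3.0, 1.0, G=1.0) == pytest.approx(0.5)

    def test_fully_polarized_flagged(self):
        with pytest.warns(UserWarning, match="outside the one-photon"):
            assert polarization(1.0, 0.0) == 1.0

    def test_zero_total_intensity(self):
        with pytest.raises(UndefinedPolarizationError):
            polarization(0.0, 0.0)

    def test_grating_factor(self):
        assert grating_factor(0.8, 1.0) == pytest.approx(0.8)
        # G rescales the perpendicular channel
        assert polarization(2.0, 1.0, G=2.0) == 0.0


class TestPerrinFit:
    def test_noiseless_round_trip_exact(self):
        series = gen_perrin(rho_ns=30.9, P0=0.40, tau_ns=2.0, noise_cv=0.0)
        fit = perrin_fit(series)
        assert fit.rho_ns == pytest.approx(30.9, rel=1e-9)
        assert fit.P0 == pytest.approx(0.40, rel=1e-9)
        # generated points satisfy the Perrin line exactly
        x = series.T_K / series.eta_poise
        y = 1 / series.P - 1 / 3
        resid = y - (fit.slope * x + fit.intercept)
        assert np.max(np.abs(resid)) < 1e-12

    def test_rigid_limit_zero_slope(self):
        T = np.array([280.0, 290.0, 300.0, 310.0])
        P = np.full(4, 0.35)
        series = PolarizationSeries(T, np.full(4, 0.01), P, tau_ns=2.0)
        with pytest.warns(UserWarning, match="rigid"):
            fit = perrin_fit(series)
        assert math.isinf(fit.rho_ns)
        assert fit.P0 == pytest.approx(0.35, rel=1e-6)

    def test_size_ordering_preserved_under_noise(self):
        # small (8.8 ns) vs large (31 ns) complexes stay ordered at 2% noise
        for seed in range(5):
            small = perrin_fit(gen_perrin(rho_ns=8.8, tau_ns=2.0,
                                          noise_cv=0.02, seed=seed))
            large = perrin_fit(gen_perrin(rho_ns=31.0, tau_ns=2.0,
                                          noise_cv=0.02, seed=seed + 100))
            assert small.rho_ns < large.rho_ns

    def test_degenerate_abscissa_rejected(self):
        series = PolarizationSeries(np.full(4, 293.15), np.full(4, 0.01),
                                    np.full(4, 0.3), tau_ns=2.0)
        with pytest.raises(ValueError, match="degenerate"):
            perrin_fit(series)


class TestCorrelationTime:
    def test_debye_relation_default(self):
        assert correlation_time(30.9) == pytest.approx(10.3, abs=0.001)

    def test_printed_convention_flag(self):
        assert correlation_time(10.0, "phi=3rho") == 30.0

    def test_round_trip(self):
        phi = correlation_time(12.0)
        assert 3 * phi == pytest.approx(12.0)


class TestLifetime:
    def test_fluorescein_calibration_point(self):
        # single 4.0 ns exponential at 100 MHz
        phase, mod = phase_modulation([100.0], [4.0], [1.0])
        assert phase[0] == pytest.approx(68.3, abs=0.05)
        assert mod[0] == pytest.approx(0.370, abs=0.001)

    def test_single_exponential_noiseless_recovery(self):
        d = gen_lifetime(taus_ns=(4.0,), fracs=(1.0,), sigma_phase=0.0,
                         sigma_mod=0.0)
        fit = lifetime_fit(d.freq_mhz, d.phase_deg, d.modulation, 1)
        assert fit.taus_ns[0] == pytest.approx(4.0, rel=1e-6)

    def test_two_component_noiseless_recovery(self):
        d = gen_lifetime(sigma_phase=0.0, sigma_mod=0.0)
        fit = lifetime_fit(d.freq_mhz, d.phase_deg, d.modulation, 2)
        assert fit.taus_ns == pytest.approx((1.5, 4.5), rel=1e-6)
        assert fit.fractions[0] == pytest.approx(0.4, rel=1e-6)

    def test_two_component_recovery_under_noise(self):
        # median over seeds at the instrument noise level (0.2 deg, 0.004)
        errs = []
        for seed in range(15):
            d = gen_lifetime(seed=seed)
            fit = lifetime_fit(d.freq_mhz, d.phase_deg, d.modulation, 2)
            errs.append(max(abs(fit.taus_ns[0] - 1.5) / 1.5,
                            abs(fit.taus_ns[1] - 4.5) / 4.5,
                            abs(fit.fractions[0] - 0.4) / 0.4))
        assert np.median(errs) < 0.05

    def test_residual_whiteness_runs_test(self):
        # correctly specified model leaves sign-random residuals
        def runs_test_pass(resid, alpha=0.05):
            signs = resid > 0
            n1, n2 = signs.sum(), (~signs).sum()
            if n1 == 0 or n2 == 0:
                return False
            runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
            mean = 1 + 2 * n1 * n2 / (n1 + n2)
            var = (2 * n1 * n2 * (2 * n1 * n2 - n1 - n2)
                   / ((n1 + n2) ** 2 * (n1 + n2 - 1)))
            z = (runs - mean) / math.sqrt(var) if var > 0 else 0.0
            return abs(z) < 1.96

        passed = 0
        n_rep = 20
        for seed in range(n_rep):
            d = gen_lifetime(seed=seed, n_freq=16)
            fit = lifetime_fit(d.freq_mhz, d.phase_deg, d.modulation, 2)
            resid = np.concatenate([fit.residual_phase_deg / 0.2,
                                    fit.residual_modulation / 0.004])
            if runs_test_pass(resid):
                passed += 1
        assert passed >= 0.9 * n_rep

    def test_collapsed_components_warn(self):
        d = gen_lifetime(taus_ns=(4.0,), fracs=(1.0,), sigma_phase=0.0,
                         sigma_mod=0.0)
        with pytest.warns(UserWarning, match="collapsed"):
            lifetime_fit(d.freq_mhz, d.phase_deg, d.modulation, 2)


class TestSucroseViscosity:
    def test_pure_water_anchor(self):
        assert sucrose_viscosity(20.0, 0.0) == pytest.approx(0.01002,
                                                             rel=1e-4)

    def test_twenty_percent_anchor(self):
        # handbook value ~1.9-2.0 cP at 20 C
        assert 0.019 <= sucrose_viscosity(20.0, 20.0) <= 0.020

    def test_monotone_decreasing_in_temperature(self):
        vals = [sucrose_viscosity(t, 20.0) for t in range(0, 61, 5)]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_monotone_increasing_in_sucrose(self):
        vals = [sucrose_viscosity(20.0, w) for w in range(0, 41, 5)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("T,w", [(-5, 20), (65, 20), (20, 45)])
    def test_out_of_table_rejected(self, T, w):
        with pytest.raises(ValueError):
            sucrose_viscosity(T, w)
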