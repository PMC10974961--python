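"""Shaft power, no-load model, cumulative integrators and batch summary."""

import numpy as np
import pytest

import nanomill as nm
from nanomill.errors import DataError, FitError, SummaryError
from nanomill.mill import NoLoadModel

from conftest import make_series


class TestShaftPower:
    def test_zero_load_gives_zero_power(self):
        assert nm.shaft_power(0.0, 0.2, 17.5) == 0.0

    def test_hand_value(self):
        # 100 N * 0.2 m * 2*pi * 17.5 rev/s
        assert nm.shaft_power(100.0, 0.2, 17.5) == pytest.approx(2199.11, abs=0.01)

    def test_linear_in_force_and_speed(self):
        p = nm.shaft_power(50.0, 0.2, 10.0)
        assert nm.shaft_power(100.0, 0.2, 10.0) == pytest.approx(2 * p)
        assert nm.shaft_power(50.0, 0.2, 20.0) == pytest.approx(2 * p)

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            nm.shaft_power(10.0, -0.1, 10.0)


class TestFitNoload:
    def test_constant_speed_gives_constant_model(self, config):
        series = make_series(np.arange(5.0), F=20.0, n_rpm=1050.0)
        model = nm.fit_noload(series, config)
        assert model.kind == "constant"
        expected = nm.shaft_power(20.0, config.load_cell_radius_m, 1050.0 / 60.0)
        assert model.predict(1050.0) == pytest.approx(expected, rel=1e-12)

    def test_two_speed_affine_exact(self, config):
        # powers on a line in speed: recover both points exactly
        n = np.array([600.0, 600.0, 1200.0, 1200.0])
        p_true = 100.0 + 30.0 * n / 60.0
        F = p_true / (config.load_cell_radius_m * 2 * np.pi * n / 60.0)
        series = make_series(np.arange(4.0), F=F, n_rpm=n)
        model = nm.fit_noload(series, config)
        assert model.kind == "affine"
        np.testing.assert_allclose(model.predict(n), p_true, rtol=1e-9)

    def test_noisy_noload_residual_below_tolerance(self, config):
        rng = np.random.default_rng(7)
        n = np.full(200, 1050.0)
        F = 20.0 * (1 + 0.01 * rng.standard_normal(200))
        series = make_series(np.arange(200.0), F=F, n_rpm=n)
        model = nm.fit_noload(series, config)
        p_scale = nm.shaft_power(20.0, config.load_cell_radius_m, 1050.0 / 60.0)
        assert model.residual_rms_W < 0.02 * p_scale

    def test_empty_segment_is_fit_error(self, config):
        series = make_series(np.arange(3.0), segment=["main", "main", "main"])
        with pytest.raises(FitError):
            nm.fit_noload(series, config)


class TestSpecificEnergyProfile:
    def test_constant_net_power_closed_form(self, config):
        # 1 kW net over 1000 s into 100 kg -> 10 kJ/kg at any step size
        for dt in (1.0, 5.0, 50.0):
            t = np.arange(0.0, 1000.0 + dt, dt)
            n = 1050.0
            F = (1000.0 + 300.0) / (
                config.load_cell_radius_m * 2 * np.pi * n / 60.0
            )
            series = make_series(t, F=F, n_rpm=n)
            noload = NoLoadModel("constant", (300.0,), 0.0, (n, n))
            prof = nm.specific_energy_profile(series, noload, 100.0, config)
            assert prof.E_M_kJ_kg[-1] == pytest.approx(10.0, rel=1e-12)

    def test_zero_net_power_gives_zero_energy(self, config):
        series = make_series(np.arange(10.0), F=5.0, n_rpm=1050.0)
        p = nm.shaft_power(5.0, config.load_cell_radius_m, 1050.0 / 60.0)
        noload = NoLoadModel("constant", (float(p),), 0.0, (1050, 1050))
        prof = nm.specific_energy_profile(series, noload, 50.0, config)
        np.testing.assert_allclose(prof.E_M_kJ_kg, 0.0, atol=1e-15)

    def test_nonpositive_mass_rejected(self, config):
        series = make_series(np.arange(3.0))
        noload = NoLoadModel("constant", (0.0,), 0.0, (0, 0))
        with pytest.raises(ValueError):
            nm.specific_energy_profile(series, noload, 0.0, config)


class TestTurnoverProfile:
    def test_constant_flow_closed_form(self, config):
        # 1 kg/s into 100 kg over 500 s -> 5 turnovers
        series = make_series(np.arange(0.0, 501.0), mdot=1.0)
        prof = nm.turnover_profile(series, 100.0, config)
        assert prof.N[-1] == pytest.approx(5.0, rel=1e-12)

    def test_zero_flow_gives_zero(self, config):
        series = make_series(np.arange(10.0), mdot=0.0, Vdot=0.0)
        prof = nm.turnover_profile(series, 100.0, config)
        np.testing.assert_array_equal(prof.N, 0.0)

    def test_volume_flow_fallback(self, config):
        series = make_series(np.arange(0.0, 601.0), mdot=np.nan, Vdot=12.0)
        prof = nm.turnover_profile(series, 100.0, config)
        expected = 12.0 * config.rho_S_kg_L / 60.0 * 600.0 / 100.0
        assert prof.N[-1] == pytest.approx(expected, rel=1e-12)

    def test_no_flow_channels_is_data_error(self, config):
        series = make_series(np.arange(3.0), mdot=np.nan, Vdot=np.nan)
        with pytest.raises(DataError):
            nm.turnover_profile(series, 100.0, config)


class TestAverageStressEnergy:
    def test_constant_speed_exact(self, config):
        series = make_series(np.arange(5.0), n_rpm=1050.0)
        kappa = config.stress_energy_constant()
        vt2 = float(config.tip_speed_m_s(1050.0)) ** 2
        assert nm.average_stress_energy(series, config) == pytest.approx(
            kappa * vt2, rel=1e-12
        )

    def test_two_segment_mean_of_squares(self, config):
        # equal sample counts at n and 2n -> mean(v^2) = v(n)^2 * (1+4)/2
        n = np.array([500.0] * 4 + [1000.0] * 4)
        series = make_series(np.arange(8.0), n_rpm=n)
        kappa = config.stress_energy_constant()
        v1 = float(config.tip_speed_m_s(500.0)) ** 2
        assert nm.average_stress_energy(series, config) == pytest.approx(
            kappa * v1 * 2.5, rel=1e-12
        )


class TestSummarizeBatch:
    def test_generator_round_trip_hits_energy_target(self, noiseless_run):
        scenario, series, noload = noiseless_run
        record = nm.summarize_batch(
            series, noload, scenario.M_kg, nm.MillConfig(), experiment="4"
        )
        assert record.E_M_kJ_kg == pytest.approx(2134, abs=1)
        assert record.SE_uNm == pytest.approx(0.61)
        assert record.n_rpm == 875 and record.Vdot_L_min == 13

    def test_constant_outlet_temperature_mean(self, config):
        series = make_series(
            np.arange(6.0),
            T_S_out=21.0,
            segment=["noload", "noload", "ramp", "main", "main", "main"],
        )
        noload = NoLoadModel("constant", (0.0,), 0.0, (1050, 1050))
        record = nm.summarize_batch(series, noload, 82.0, config)
        assert record.T_S_out_C == 21.0

    def test_missing_main_segment_errors(self, config):
        series = make_series(np.arange(4.0), segment=["noload"] * 2 + ["ramp"] * 2)
        noload = NoLoadModel("constant", (0.0,), 0.0, (1050, 1050))
        with pytest.raises(SummaryError):
            nm.summarize_batch(series, noload, 82.0, config)

    def test_zero_duration_main_segment_errors(self, config):
        series = make_series(np.arange(4.0), segment=["noload"] * 3 + ["main"])
        noload = NoLoadModel("constant", (0.0,), 0.0, (1050, 1050))
        with pytest.raises(SummaryError):
            nm.summarize_batch(series, noload, 82.0, config)
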