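"""Synthetic run generator: protocol compliance, determinism, faults, IPC."""

import dataclasses

import numpy as np
import pytest

import nanomill as nm
from nanomill.errors import ScenarioError
from nanomill.simulate import (
    NoiseSpec,
    RunScenario,
    inject_fault,
    recorded_batch_mass,
    sample_ipc,
    scenarios_from_table,
)


@pytest.fixture(scope="module")
def short_scenario():
    return RunScenario(name="s", M_kg=82.0, target_E_M_kJ_kg=400.0, dt_s=5.0)


class TestProtocol:
    def test_flow_is_start_flow_until_three_turnovers(self, short_scenario, config):
        series = nm.generate_run(short_scenario, config)
        prof = nm.turnover_profile(series, short_scenario.M_kg, config)
        proc = series.segment_mask("ramp", "main")
        early = proc & (prof.N < 3.0)
        np.testing.assert_allclose(series.Vdot_L_min[early], 5.0, rtol=1e-12)

    def test_noload_segment_has_zero_flow(self, short_scenario, config):
        series = nm.generate_run(short_scenario, config)
        noload = series.segment_mask("noload")
        assert noload.any()
        np.testing.assert_array_equal(series.mdot_kg_s[noload], 0.0)

    def test_main_segment_at_set_flow(self, short_scenario, config):
        series = nm.generate_run(short_scenario, config)
        main = series.segment_mask("main")
        np.testing.assert_allclose(
            series.Vdot_L_min[main], short_scenario.Vdot_set_L_min, rtol=1e-12
        )

    def test_energy_target_reached_within_a_step(self, short_scenario, config):
        series = nm.generate_run(short_scenario, config)
        noload = nm.fit_noload(series, config)
        prof = nm.specific_energy_profile(series, noload, short_scenario.M_kg, config)
        assert prof.E_M_kJ_kg[-1] == pytest.approx(400.0, rel=1e-3)

    def test_unreachable_target_is_scenario_error(self, config):
        with pytest.raises(ScenarioError):
            nm.generate_run(
                RunScenario(net_power_W=0.0, target_E_M_kJ_kg=100.0), config
            )

    def test_noise_requires_seed(self, config):
        with pytest.raises(ScenarioError):
            nm.generate_run(RunScenario(noise=NoiseSpec(), seed=None), config)


class TestDeterminism:
    def test_same_seed_bit_identical(self, config):
        sc = RunScenario(target_E_M_kJ_kg=200.0, dt_s=5.0, noise=NoiseSpec(), seed=42)
        a = nm.generate_run(sc, config)
        b = nm.generate_run(sc, config)
        np.testing.assert_array_equal(a.F_N, b.F_N)
        np.testing.assert_array_equal(a.T_S_out_C, b.T_S_out_C)

    def test_different_seed_differs(self, config):
        sc1 = RunScenario(target_E_M_kJ_kg=200.0, dt_s=5.0, noise=NoiseSpec(), seed=1)
        sc2 = dataclasses.replace(sc1, seed=2)
        assert not np.array_equal(
            nm.generate_run(sc1, config).F_N, nm.generate_run(sc2, config).F_N
        )


class TestSampleIPC:
    def test_noise_disabled_is_exact_prediction(self, fitted_corr):
        x, pdi = sample_ipc(2000.0, fitted_corr, noise=False)
        assert x == nm.predict_size(fitted_corr, 2000.0)
        assert pdi == pytest.approx(0.11)

    def test_size_rsd_matches_analytical_precision(self, fitted_corr):
        rng = np.random.default_rng(5)
        draws = np.array(
            [sample_ipc(2000.0, fitted_corr, seed=rng)[0] for _ in range(10_000)]
        )
        rsd = 100 * draws.std(ddof=1) / draws.mean()
        assert 0.8 <= rsd <= 1.0

    def test_pdi_plateau_mean(self, fitted_corr):
        rng = np.random.default_rng(6)
        draws = np.array(
            [sample_ipc(2000.0, fitted_corr, seed=rng)[1] for _ in range(10_000)]
        )
        assert abs(draws.mean() - 0.11) < 0.005


class TestCampaign:
    def test_reference_mirror_campaign(self, reference_records, config, fitted_corr):
        scenarios = scenarios_from_table(reference_records)
        table = nm.generate_campaign(scenarios, config, fitted_corr, seed=77)
        assert len(table) == 22
        corr = nm.fit_size_energy(table)
        assert corr.exponent < 0

    def test_empty_design_gives_empty_table(self, config, fitted_corr):
        assert nm.generate_campaign([], config, fitted_corr, seed=1) == []

    def test_same_seed_reproduces_table(self, reference_records, config, fitted_corr):
        scenarios = scenarios_from_table(reference_records[:4])
        t1 = nm.generate_campaign(scenarios, config, fitted_corr, seed=9)
        t2 = nm.generate_campaign(
            scenarios_from_table(reference_records[:4]), config, fitted_corr, seed=9
        )
        assert [r.to_dict() for r in t1] == [r.to_dict() for r in t2]


@pytest.fixture(scope="module")
def clean(config):
    sc = RunScenario(name="f", M_kg=82.0, target_E_M_kJ_kg=400.0, dt_s=5.0)
    series = nm.generate_run(sc, config)
    noload = nm.fit_noload(series, config)
    prof = nm.specific_energy_profile(series, noload, 82.0, config)
    return sc, series, prof


class TestFaults:
    def test_massflow_dropout_lowers_turnovers(self, clean, config):
        sc, series, prof = clean
        t_mid = series.t_s[len(series) // 2]
        faulty = inject_fault(series, "massflow_dropout", start_s=t_mid, duration_s=600.0)
        prof_f = nm.turnover_profile(faulty, sc.M_kg, config)
        assert prof_f.N[-1] < prof.N[-1]

    def test_biased_noload_lowers_energy(self, clean, config):
        sc, series, prof = clean
        faulty = inject_fault(series, "biased_noload", bias=0.10)
        noload_f = nm.fit_noload(faulty, config)
        prof_f = nm.specific_energy_profile(faulty, noload_f, sc.M_kg, config)
        assert prof_f.E_M_kJ_kg[-1] < prof.E_M_kJ_kg[-1]

    def test_wrong_batch_mass_scales_exactly(self, clean, config):
        sc, series, prof = clean
        faulty = inject_fault(series, "wrong_batch_mass", factor=0.9)
        m_rec = recorded_batch_mass(faulty, sc.M_kg)
        assert m_rec == pytest.approx(0.9 * sc.M_kg)
        noload = nm.fit_noload(faulty, config)
        prof_f = nm.specific_energy_profile(faulty, noload, m_rec, config)
        assert prof_f.E_M_kJ_kg[-1] == pytest.approx(
            prof.E_M_kJ_kg[-1] / 0.9, rel=1e-12
        )
        assert prof_f.N[-1] == pytest.approx(prof.N[-1] / 0.9, rel=1e-12)

    def test_original_series_untouched(self, clean):
        _, series, _ = clean
        before = series.mdot_kg_s.copy()
        inject_fault(series, "massflow_dropout", start_s=0.0, duration_s=1e9)
        np.testing.assert_array_equal(series.mdot_kg_s, before)

    def test_unknown_fault_kind_rejected(self, clean):
        _, series, _ = clean
        with pytest.raises(ValueError):
            inject_fault(series, "gremlins")

    def test_fault_recorded_in_metadata(self, clean):
        _, series, _ = clean
        faulty = inject_fault(series, "biased_noload", bias=0.05)
        assert faulty.metadata["faults"][0]["kind"] == "biased_noload"
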