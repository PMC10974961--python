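"""Shared fixtures: reference table, config, fitted correlation, synthetic runs."""

import numpy as np
import pytest
from hypothesis import settings

import nanomill as nm
from nanomill.simulate import RunScenario

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_records():
    return nm.load_reference_table()


@pytest.fixture(scope="session")
def config():
    return nm.MillConfig()


@pytest.fixture(scope="session")
def fitted_corr(reference_records):
    return nm.fit_size_energy(reference_records)


@pytest.fixture(scope="session")
def default_space():
    return nm.default_design_space()


@pytest.fixture(scope="session")
def noiseless_run(config):
    """A noiseless run mirroring the low-speed batch: 875 rpm, 13 L/min,
    82 kg, 2134 kJ/kg target; coarse grid keeps it fast."""
    scenario = RunScenario(
        name="row4",
        M_kg=82.0,
        n_rpm=875.0,
        Vdot_set_L_min=13.0,
        T_C_in_C=8.0,
        target_E_M_kJ_kg=2134.0,
        speed_cubed_power=True,
        dt_s=20.0,
    )
    series = nm.generate_run(scenario, config)
    noload = nm.fit_noload(series, config)
    return scenario, series, noload


def make_series(
    t,
    F=10.0,
    n_rpm=1050.0,
    mdot=0.3,
    Vdot=16.0,
    T_S_in=20.0,
    T_S_out=21.0,
    T_C_in=9.0,
    T_C_out=10.0,
    mdot_C=0.5,
    segment=None,
):
    """Small hand-built sensor series with broadcastable channels."""
    t = np.asarray(t, dtype=float)

    def full(v):
        return np.broadcast_to(np.asarray(v, dtype=float), t.shape).copy()

    return nm.SensorTimeSeries(
        t_s=t,
        F_N=full(F),
        n_rpm=full(n_rpm),
        mdot_kg_s=full(mdot),
        Vdot_L_min=full(Vdot),
        T_S_in_C=full(T_S_in),
        T_S_out_C=full(T_S_out),
        T_C_in_C=full(T_C_in),
        T_C_out_C=full(T_C_out),
        mdot_C_kg_s=full(mdot_C),
        segment=None if segment is None else np.asarray(segment, dtype=object),
    )
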