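"""Synthetic mill runs and campaigns with the statistical structure the
analysis assumes.

A generated run follows the plant protocol: a pre-run no-load power
measurement at set speed with zero suspension flow, processing started at a
low 5 L/min volume flow, a linear ramp to the set flow once three batch
turnover cycles are reached, then constant flow until the target
mass-specific energy.  Temperature channels are constructed to satisfy the
chamber energy balance exactly in noiseless mode: a configurable fraction of
the net agitator power is carried off by the jacket coolant and the
remainder heats the suspension stream.

Net shaft power is a scenario setpoint (optionally scaled with speed cubed,
as stirred-media power draw roughly is); real torque dynamics such as the
viscosity rise while particles shrink are not modeled, which the series
metadata flags.  Measurement noise is multiplicative Gaussian per channel,
defaulting to 1% for plant sensors; in-process size and PdI measurements use
the validated analytical precisions (0.9% and 7.4% RSD).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .correlation import SizeEnergyCorrelation, predict_size
from .errors import ScenarioError
from .io import BatchRecord, MillConfig, SensorTimeSeries
from .mill import NoLoadModel, fit_noload, summarize_batch

#: Analytical intermediate precisions of the particle-size method (RSD).
SIZE_RSD = 0.009
PDI_RSD = 0.074
#: PdI plateau level and the specific energy above which it holds.
PDI_PLATEAU = 0.11
PDI_PLATEAU_E_M = 200.0

#: Protocol constants: starting volume flow and the turnover count that
#: triggers the ramp to the set flow.
START_VDOT_L_MIN = 5.0
RAMP_TRIGGER_TURNOVERS = 3.0

FAULT_KINDS = ("wrong_batch_mass", "biased_noload", "massflow_dropout")


@dataclass
class NoiseSpec:
    """Multiplicative Gaussian sensor noise, one RSD per channel."""

    rsd: dict = field(
        default_factory=lambda: {
            "F_N": 0.01,
            "n_rpm": 0.01,
            "mdot_kg_s": 0.01,
            "Vdot_L_min": 0.01,
            "T_S_in_C": 0.01,
            "T_S_out_C": 0.01,
            "T_C_in_C": 0.01,
            "T_C_out_C": 0.01,
            "mdot_C_kg_s": 0.01,
        }
    )


@dataclass
class RunScenario:
    """Inputs of one synthetic run: set parameters plus generator knobs."""

    name: str = "run"
    M_kg: float = 82.0
    n_rpm: float = 1050.0
    Vdot_set_L_min: float = 16.0
    T_C_in_C: float = 9.0
    target_E_M_kJ_kg: float = 2134.0
    net_power_W: float = 2200.0
    noload_power_W: float = 300.0
    speed_cubed_power: bool = False
    power_reference_rpm: float = 1050.0
    T_S_in_C: float = 20.0
    mdot_C_kg_s: float = 0.5
    coolant_fraction: float = 0.7
    dt_s: float = 1.0
    noload_duration_s: float = 60.0
    ramp_duration_s: float = 60.0
    x90_3_um: Optional[float] = None
    noise: Optional[NoiseSpec] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.target_E_M_kJ_kg > 0:
            raise ScenarioError("target E_M must be positive")
        if not self.dt_s > 0:
            raise ScenarioError("time step must be positive")
        if not self.M_kg > 0:
            raise ScenarioError("batch mass must be positive")
        if not (0.0 <= self.coolant_fraction <= 1.0):
            raise ScenarioError("coolant_fraction must lie in [0, 1]")

    def net_power_at_speed(self) -> float:
        if self.speed_cubed_power:
            return self.net_power_W * (self.n_rpm / self.power_reference_rpm) ** 3
        return self.net_power_W

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def generate_run(scenario: RunScenario, config: MillConfig) -> SensorTimeSeries:
    """Generate the sensor series of one run following the plant protocol.

    In noiseless mode the temperature channels close the energy balance
    exactly and the run is a pure function of (scenario, config); with noise
    the scenario seed makes it a pure function of (scenario, seed, config).
    """
    dt = scenario.dt_s
    if scenario.noise is not None and scenario.seed is None:
        raise ScenarioError("a seed is mandatory when noise is enabled")
    p_net = scenario.net_power_at_speed()
    if not p_net > 0:
        raise ScenarioError("net power must be positive to reach the energy target")
    p0 = scenario.noload_power_W
    n_rev_s = scenario.n_rpm / 60.0
    omega_r = config.load_cell_radius_m * 2.0 * np.pi * n_rev_s

    rho = config.rho_S_kg_L
    mdot_start = START_VDOT_L_MIN * rho / 60.0
    mdot_set = scenario.Vdot_set_L_min * rho / 60.0

    k_noload = max(2, int(round(scenario.noload_duration_s / dt)))
    # processing duration: rectangle-rule sum of constant net power reaches
    # the target after ceil(target / (P dt / 1000 M)) samples
    j_proc = int(np.ceil(scenario.target_E_M_kJ_kg * 1000.0 * scenario.M_kg / (p_net * dt)))
    # ramp trigger: first processing sample at which N >= 3 under start flow
    i_star = int(np.ceil(RAMP_TRIGGER_TURNOVERS * scenario.M_kg / (mdot_start * dt)))
    k_ramp = max(1, int(round(scenario.ramp_duration_s / dt)))
    if i_star + k_ramp >= j_proc:
        raise ScenarioError(
            "energy target reached before the flow ramp completes; "
            "increase the target or the net power"
        )

    n_total = k_noload + j_proc
    t = np.arange(n_total, dtype=float) * dt
    segment = np.empty(n_total, dtype=object)
    segment[:k_noload] = "noload"
    segment[k_noload : k_noload + i_star + k_ramp] = "ramp"
    segment[k_noload + i_star + k_ramp :] = "main"

    n_rpm = np.full(n_total, scenario.n_rpm)
    F = np.empty(n_total)
    F[:k_noload] = p0 / omega_r
    F[k_noload:] = (p0 + p_net) / omega_r

    mdot = np.zeros(n_total)
    flow = np.full(j_proc, mdot_set)
    flow[: i_star] = mdot_start
    ramp_steps = np.arange(1, k_ramp + 1, dtype=float)
    flow[i_star : i_star + k_ramp] = mdot_start + (mdot_set - mdot_start) * ramp_steps / k_ramp
    mdot[k_noload:] = flow
    Vdot = mdot * 60.0 / rho

    # temperatures satisfying the chamber energy balance per sample
    T_S_in = np.full(n_total, scenario.T_S_in_C)
    T_C_in = np.full(n_total, scenario.T_C_in_C)
    mdot_C = np.full(n_total, scenario.mdot_C_kg_s)
    q_agi = np.zeros(n_total)
    q_agi[k_noload:] = p_net
    q_coolant = scenario.coolant_fraction * q_agi
    T_C_out = T_C_in + q_coolant / (scenario.mdot_C_kg_s * config.cp_C_J_kgK)
    T_S_out = T_S_in.copy()
    proc = np.zeros(n_total, dtype=bool)
    proc[k_noload:] = True
    alphaA = config.loss_coefficient_W_K
    flow_capacity = mdot[proc] * config.cp_S_J_kgK
    # loss surface taken as T_S,out keeps the balance linear; signs match
    # the outlet-temperature predictor in the energy module exactly:
    # T_out (m cp - alphaA) = (1-f) Q_Agi - alphaA T_Atm + T_in m cp
    T_S_out[proc] = (
        (1.0 - scenario.coolant_fraction) * q_agi[proc]
        - alphaA * config.T_Atm_C
        + T_S_in[proc] * flow_capacity
    ) / (flow_capacity - alphaA)

    channels = {
        "t_s": t,
        "F_N": F,
        "n_rpm": n_rpm,
        "mdot_kg_s": mdot,
        "Vdot_L_min": Vdot,
        "T_S_in_C": T_S_in,
        "T_S_out_C": T_S_out,
        "T_C_in_C": T_C_in,
        "T_C_out_C": T_C_out,
        "mdot_C_kg_s": mdot_C,
    }
    if scenario.noise is not None:
        rng = np.random.default_rng(scenario.seed)
        for name, rsd in scenario.noise.rsd.items():
            if rsd > 0 and name in channels:
                channels[name] = channels[name] * (
                    1.0 + rsd * rng.standard_normal(n_total)
                )

    return SensorTimeSeries(
        **channels,
        segment=segment,
        metadata={
            "scenario": scenario.to_dict(),
            "seed": scenario.seed,
            "power_model": "constant net-power setpoint (stand-in; no torque dynamics)",
        },
    )


def sample_ipc(
    E_M_kJ_kg: float,
    corr: SizeEnergyCorrelation,
    seed=None,
    noise: bool = True,
    size_rsd: float = SIZE_RSD,
    pdi_rsd: float = PDI_RSD,
):
    """Draw one in-process (x_PCS, PdI) measurement at the given energy.

    Size is the correlation prediction perturbed by the analytical precision
    (multiplicative Gaussian).  PdI sits on its plateau above the plateau
    energy and rises toward coarser, broader distributions below it.
    """
    x_true = predict_size(corr, E_M_kJ_kg, warn_extrapolation=False)
    pdi_mean = PDI_PLATEAU
    if E_M_kJ_kg < PDI_PLATEAU_E_M:
        pdi_mean = PDI_PLATEAU * (PDI_PLATEAU_E_M / E_M_kJ_kg) ** 0.5
    if not noise:
        return float(x_true), float(pdi_mean)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = x_true * (1.0 + size_rsd * rng.standard_normal())
    pdi = pdi_mean * (1.0 + pdi_rsd * rng.standard_normal())
    return float(x), float(min(max(pdi, 0.0), 1.0))


def generate_campaign(
    scenarios: Sequence[RunScenario],
    config: MillConfig,
    corr: SizeEnergyCorrelation,
    seed: Optional[int] = None,
) -> list[BatchRecord]:
    """Run every scenario and assemble the resulting batch table.

    Each run is generated, its no-load model fitted from its own no-load
    segment, the cumulative parameters summarized, and an end-of-batch IPC
    sample drawn from the generating correlation.  Per-run seeds are spawned
    deterministically from ``seed``.
    """
    records: list[BatchRecord] = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(scenarios))
    for scenario, child in zip(scenarios, children):
        rng = np.random.default_rng(child)
        if scenario.noise is not None and scenario.seed is None:
            scenario = dataclasses.replace(
                scenario, seed=int(child.generate_state(1)[0] % 2**31)
            )
        try:
            series = generate_run(scenario, config)
            noload = fit_noload(series, config)
            record = summarize_batch(
                series,
                noload,
                scenario.M_kg,
                config,
                experiment=scenario.name,
                x90_3_um=scenario.x90_3_um,
            )
        except Exception as exc:
            raise ScenarioError(f"scenario {scenario.name!r}: {exc}") from exc
        x, pdi = sample_ipc(
            record.E_M_kJ_kg, corr, seed=rng, noise=scenario.noise is not None
        )
        record.x_PCS_nm = float(np.round(x))
        record.PdI = float(np.round(pdi, 2))
        records.append(record)
    return records


def scenarios_from_table(
    records: Sequence[BatchRecord],
    max_samples_per_run: int = 4000,
    noise: bool = True,
    net_power_W: float = 2200.0,
) -> list[RunScenario]:
    """Scenarios mirroring the set parameters of a batch table.

    Batch mass, shaft speed, set volume flow, coolant inlet temperature and
    the energy target are taken from each record; net power scales with
    speed cubed around the 1050 rpm reference.  The time step is widened per
    scenario so no run exceeds ``max_samples_per_run`` processing samples
    (discretization error stays far below the reported precision).
    """
    scenarios = []
    for r in records:
        p_net = net_power_W * (r.n_rpm / 1050.0) ** 3
        t_proc = r.E_M_kJ_kg * 1000.0 * r.M_kg / p_net
        dt = max(1.0, np.ceil(t_proc / max_samples_per_run))
        scenarios.append(
            RunScenario(
                name=r.experiment,
                M_kg=r.M_kg,
                n_rpm=r.n_rpm,
                Vdot_set_L_min=r.Vdot_L_min,
                T_C_in_C=r.T_C_in_C,
                target_E_M_kJ_kg=r.E_M_kJ_kg,
                net_power_W=net_power_W,
                speed_cubed_power=True,
                dt_s=float(dt),
                x90_3_um=r.x90_3_um,
                noise=NoiseSpec() if noise else None,
            )
        )
    return scenarios


def inject_fault(series: SensorTimeSeries, kind: str, **params) -> SensorTimeSeries:
    """Return a copy of the series with one operational fault applied.

    ``wrong_batch_mass``: the batch mass was mis-weighed/mis-entered; the
    recorded mass is ``factor`` times the true one (metadata only -- the
    sensors are untouched, downstream summaries using the recorded mass
    scale accordingly).
    ``biased_noload``: the no-load measurement read high or low by
    ``bias`` (relative); the no-load segment force is scaled.
    ``massflow_dropout``: the mass-flow sensor reports zero over the window
    ``[start_s, start_s + duration_s)``.
    """
    if kind not in FAULT_KINDS:
        raise ValueError(f"unknown fault kind {kind!r}; known: {FAULT_KINDS}")
    out = series.copy()
    fault = {"kind": kind, **params}
    if kind == "wrong_batch_mass":
        factor = float(params.get("factor", 0.9))
        if not factor > 0:
            raise ValueError("mass factor must be positive")
        out.metadata["recorded_mass_factor"] = factor
    elif kind == "biased_noload":
        bias = float(params.get("bias", 0.10))
        mask = out.segment_mask("noload")
        out.F_N[mask] *= 1.0 + bias
    elif kind == "massflow_dropout":
        start = float(params.get("start_s", out.t_s[len(out) // 2]))
        duration = float(params.get("duration_s", 60.0))
        mask = (out.t_s >= start) & (out.t_s < start + duration)
        out.mdot_kg_s[mask] = 0.0
        out.Vdot_L_min[mask] = 0.0
    out.metadata.setdefault("faults", []).append(fault)
    return out


def recorded_batch_mass(series: SensorTimeSeries, true_M_kg: float) -> float:
    """Batch mass as recorded for the run, including any weighing fault."""
    return true_M_kg * float(series.metadata.get("recorded_mass_factor", 1.0))
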