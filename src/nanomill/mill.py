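"""Stress-energy process model of the wet stirred media mill.

The model tracks the measurable surrogates of the stressing conditions in
the grinding chamber:

* shaft power ``P = F * r * 2 * pi * n`` from the load-cell force ``F``,
  the load-cell lever radius ``r`` and the shaft speed ``n`` (rev/s);
* cumulative mass-specific energy
  ``E_M,i = E_M,i-1 + (P_i - P0_i) * (t_i - t_{i-1}) / M``,
  the net mechanical energy per kilogram of suspension (kJ/kg);
* average stress energy ``SE = kappa * mean(v_t^2)``, the kinetic energy
  scale of a single bead collision (uNm), quadratic in tip speed;
* turnover cycles ``N_i = N_{i-1} + mdot_i * (t_i - t_{i-1}) / M``, the
  number of times the batch mass has passed through the chamber.

The discrete recursions are evaluated exactly as written (rectangle rule
with the sample at the right end of each interval); the test suite bounds
the discretization error against a fine-grid oracle.  Negative instantaneous
net power (P below the no-load model) is retained, not clamped, and logged
as a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DataError, FitError, SummaryError
from .io import BatchRecord, MillConfig, SensorTimeSeries

log = logging.getLogger(__name__)


def shaft_power(F_N, r_m: float, n_rev_s) -> np.ndarray:
    """Agitator shaft power P = F * r * 2*pi*n in W (n in rev/s)."""
    if not r_m > 0:
        raise ValueError("load-cell radius must be positive")
    n = np.asarray(n_rev_s, dtype=float)
    if np.any(n[np.isfinite(n)] < 0):
        raise ValueError("shaft speed must be non-negative")
    return np.asarray(F_N, dtype=float) * r_m * 2.0 * np.pi * n


@dataclass
class NoLoadModel:
    """No-load power draw P0 as a function of shaft speed.

    ``kind`` is ``constant`` (speed variation below 1% in the fitted
    segment) or ``affine`` (P0 = c0 + c1 * n, n in rev/s).
    """

    kind: str
    coefficients: tuple
    residual_rms_W: float
    speed_range_rpm: tuple

    def predict(self, n_rpm) -> np.ndarray:
        n_rev_s = np.asarray(n_rpm, dtype=float) / 60.0
        if self.kind == "constant":
            return np.full_like(n_rev_s, self.coefficients[0])
        c0, c1 = self.coefficients
        return c0 + c1 * n_rev_s


def fit_noload(
    series: SensorTimeSeries, config: MillConfig, segment_label: str = "noload"
) -> NoLoadModel:
    """Fit the no-load power model from the pre-run no-load segment.

    Uses the samples labelled ``segment_label`` when segment labels exist,
    else the whole series.  A constant model is fitted when the observed
    speed varies by less than 1%; otherwise an affine-in-speed model.
    """
    mask = series.segment_mask(segment_label)
    if mask.sum() < 2:
        raise FitError("no-load segment must contain at least 2 samples")
    n_rpm = series.n_rpm[mask]
    P = shaft_power(series.F_N[mask], config.load_cell_radius_m, n_rpm / 60.0)
    span = (np.max(n_rpm) - np.min(n_rpm)) / max(np.mean(n_rpm), 1e-12)
    if span < 0.01:
        p0 = float(np.mean(P))
        resid = float(np.sqrt(np.mean((P - p0) ** 2)))
        model = NoLoadModel(
            "constant", (p0,), resid, (float(np.min(n_rpm)), float(np.max(n_rpm)))
        )
    else:
        c1, c0 = np.polyfit(n_rpm / 60.0, P, 1)
        pred = c0 + c1 * n_rpm / 60.0
        resid = float(np.sqrt(np.mean((P - pred) ** 2)))
        model = NoLoadModel(
            "affine",
            (float(c0), float(c1)),
            resid,
            (float(np.min(n_rpm)), float(np.max(n_rpm))),
        )
    lo, hi = model.speed_range_rpm
    if np.min(model.predict(np.array([lo, hi]))) < 0:
        raise FitError("fitted no-load model predicts negative power in range")
    return model


@dataclass
class CumulativeProfile:
    """Per-sample cumulative process parameters of one run."""

    t_s: np.ndarray
    P_W: np.ndarray
    P0_W: np.ndarray
    E_M_kJ_kg: np.ndarray
    N: np.ndarray
    SE_uNm: np.ndarray  # running average stress energy up to each sample

    def __post_init__(self) -> None:
        n = self.t_s.size
        for name in ("P_W", "P0_W", "E_M_kJ_kg", "N", "SE_uNm"):
            if getattr(self, name).size != n:
                raise DataError(f"profile channel {name} length mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t_s,
                "P_W": self.P_W,
                "P0_W": self.P0_W,
                "E_M_kJ_kg": self.E_M_kJ_kg,
                "N": self.N,
                "SE_uNm": self.SE_uNm,
            }
        )


def _mass_flow(series: SensorTimeSeries, config: Optional[MillConfig]) -> np.ndarray:
    """Suspension mass flow in kg/s, derived from volume flow if needed."""
    if series.has_channel("mdot_kg_s"):
        return series.mdot_kg_s
    if series.has_channel("Vdot_L_min"):
        if config is None:
            raise DataError(
                "mass flow channel absent: need a MillConfig with rho_S_kg_L "
                "to derive it from volume flow"
            )
        return series.Vdot_L_min * config.rho_S_kg_L / 60.0
    raise DataError("both mass-flow and volume-flow channels are absent")


def _profile(
    series: SensorTimeSeries,
    noload: NoLoadModel,
    M_kg: float,
    config: MillConfig,
) -> CumulativeProfile:
    if not M_kg > 0:
        raise ValueError("batch mass M must be positive")
    t = series.t_s
    P = shaft_power(series.F_N, config.load_cell_radius_m, series.n_rpm / 60.0)
    P0 = np.asarray(noload.predict(series.n_rpm), dtype=float)
    net = P - P0
    dt = np.diff(t)

    proc = series.segment_mask("ramp", "main")
    if np.any(net[proc] < 0):
        k = int(np.where(proc & (net < 0))[0][0])
        log.warning(
            "instantaneous net power below no-load model at sample %d "
            "(%.1f W); retained without clamping",
            k,
            net[k],
        )

    E = np.zeros_like(t)
    E[1:] = np.cumsum(net[1:] * dt) / (M_kg * 1000.0)  # kJ/kg

    mdot = _mass_flow(series, config)
    N = np.zeros_like(t)
    N[1:] = np.cumsum(mdot[1:] * dt) / M_kg

    vt2 = config.tip_speed_m_s(series.n_rpm) ** 2
    kappa = config.stress_energy_constant()
    running = np.cumsum(vt2) / np.arange(1, t.size + 1)
    return CumulativeProfile(t, P, P0, E, N, kappa * running)


def specific_energy_profile(
    series: SensorTimeSeries,
    noload: NoLoadModel,
    M_kg: float,
    config: MillConfig,
) -> CumulativeProfile:
    """Cumulative mass-specific energy profile E_M,i in kJ/kg.

    Rectangle-rule cumulative sum of net power over time divided by batch
    mass; non-decreasing whenever P_i >= P0_i throughout.
    """
    return _profile(series, noload, M_kg, config)


def turnover_profile(
    series: SensorTimeSeries,
    M_kg: float,
    config: Optional[MillConfig] = None,
    noload: Optional[NoLoadModel] = None,
) -> CumulativeProfile:
    """Cumulative turnover cycles N_i (transported mass / batch mass).

    When no no-load model is supplied a zero-power placeholder is used; the
    energy channels of the returned profile are then not meaningful.
    """
    if not M_kg > 0:
        raise ValueError("batch mass M must be positive")
    cfg = config if config is not None else MillConfig()
    nl = noload if noload is not None else NoLoadModel("constant", (0.0,), 0.0, (0, 0))
    return _profile(series, nl, M_kg, cfg)


def average_stress_energy(
    series: SensorTimeSeries,
    config: MillConfig,
    processing_only: bool = True,
) -> float:
    """Average stress energy SE = kappa * mean(v_t^2) in uNm.

    By default averages over the processing samples (ramp + main) when
    segment labels exist; the pre-run no-load measurement is not part of the
    milling duration.  Scales with the square of a uniform speed multiplier.
    """
    kappa = config.stress_energy_constant()
    if processing_only and series.segment is not None:
        mask = series.segment_mask("ramp", "main")
        if not mask.any():
            mask = np.ones(len(series), dtype=bool)
    else:
        mask = np.ones(len(series), dtype=bool)
    vt2 = config.tip_speed_m_s(series.n_rpm[mask]) ** 2
    return float(kappa * np.mean(vt2))


#: Decimal places of the batch-table reporting precision.
_TABLE_PRECISION = {
    "T_S_out_C": 0,
    "E_M_kJ_kg": 0,
    "SE_uNm": 2,
    "N": 0,
    "T_C_in_C": 0,
    "Vdot_L_min": 0,
    "n_rpm": 0,
}


def summarize_batch(
    series: SensorTimeSeries,
    noload: NoLoadModel,
    M_kg: float,
    config: MillConfig,
    experiment: str = "run",
    x90_3_um: Optional[float] = None,
    round_to_table_precision: bool = True,
) -> BatchRecord:
    """End-of-run batch record (without quality attributes).

    E_M, N and SE are evaluated at the end of the run; the average
    suspension outlet temperature is the arithmetic mean over the main
    (post-ramp) segment, matching how a steady processing temperature is
    reported.  Values are rounded to the batch-table reporting precision
    unless ``round_to_table_precision`` is disabled.
    """
    if series.segment is None or not series.segment_mask("main").any():
        raise SummaryError("run has no main segment to summarize")
    main = series.segment_mask("main")
    t_main = series.t_s[main]
    if t_main.size < 2 or t_main[-1] - t_main[0] <= 0:
        raise SummaryError("main segment has zero duration")

    profile = _profile(series, noload, M_kg, config)
    proc = series.segment_mask("ramp", "main")
    values = {
        "E_M_kJ_kg": float(profile.E_M_kJ_kg[-1]),
        "N": float(profile.N[-1]),
        "SE_uNm": average_stress_energy(series, config),
        "T_S_out_C": float(np.mean(series.T_S_out_C[main])),
        "n_rpm": float(np.median(series.n_rpm[proc])),
        "Vdot_L_min": float(np.max(series.Vdot_L_min[main])),
        "T_C_in_C": float(np.mean(series.T_C_in_C[proc]))
        if series.has_channel("T_C_in_C")
        else np.nan,
    }
    if round_to_table_precision:
        for key, nd in _TABLE_PRECISION.items():
            raw = values[key]
            if np.isfinite(raw):
                rounded = float(np.round(raw, nd))
                # never round a positive quantity down to zero
                values[key] = rounded if rounded != 0.0 or raw == 0.0 else raw
    return BatchRecord(
        experiment=str(experiment),
        x90_3_um=x90_3_um,
        M_kg=M_kg,
        n_rpm=values["n_rpm"],
        Vdot_L_min=values["Vdot_L_min"],
        T_C_in_C=values["T_C_in_C"],
        T_S_out_C=values["T_S_out_C"],
        E_M_kJ_kg=values["E_M_kJ_kg"],
        SE_uNm=values["SE_uNm"],
        N=values["N"],
    )
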