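"""Steady-flow energy balance of the suspension in the grinding chamber.

The balance over the chamber reads

    Q_S,out - Q_S,in = (Q_C,in - Q_C,out) + Q_Agi - Q_Atm

with the suspension side ``mdot * cp_S * (T_S,out - T_S,in)``, the agitator
input ``P - P0`` (net shaft power, all of which is dissipated into the
chamber contents), the coolant side ``mdot_C * cp_C * (T_C,out - T_C,in)``
(heat picked up by the jacket coolant) and an atmospheric loss
``alpha*A*(T_Atm - T_surface)`` lumped into a single loss coefficient in
W/K.  Heat generated at the shaft bearings and the thermal hold-up of the
chamber contents are neglected; the balance is quasi-steady per sample.

Solving for the suspension outlet temperature gives the predictor used for
process control:

    T_S,out = [mdot_C*cp_C*(T_C,in - T_C,out) + Q_Agi - Q_Atm] / (mdot*cp_S)
              + T_S,in
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import BalanceError, DataError
from .io import MillConfig, SensorTimeSeries
from .mill import NoLoadModel, fit_noload, shaft_power


def suspension_heat(mdot_kg_s, cp_S_J_kgK, T_in_C, T_out_C):
    """Net heat flow into the suspension stream, W (positive when it warms)."""
    return (
        np.asarray(mdot_kg_s, dtype=float)
        * cp_S_J_kgK
        * (np.asarray(T_out_C, dtype=float) - np.asarray(T_in_C, dtype=float))
    )


def agitator_heat(P_W, P0_W):
    """Mechanical energy input of the agitator: net shaft power P - P0, W."""
    return np.asarray(P_W, dtype=float) - np.asarray(P0_W, dtype=float)


def coolant_heat(mdot_C_kg_s, cp_C_J_kgK, T_C_in_C, T_C_out_C):
    """Heat removed by the jacket coolant, W (positive when coolant warms)."""
    return (
        np.asarray(mdot_C_kg_s, dtype=float)
        * cp_C_J_kgK
        * (np.asarray(T_C_out_C, dtype=float) - np.asarray(T_C_in_C, dtype=float))
    )


def atmospheric_loss(loss_coefficient_W_K, T_Atm_C, T_surface_C):
    """Heat flow from the atmosphere into the chamber surface, W.

    Sign convention: positive when the atmosphere is warmer than the
    surface; the balance subtracts this term, so a warm chamber in cool air
    (negative value here) adds to the suspension-side heat.
    """
    if loss_coefficient_W_K < 0:
        raise ValueError("loss coefficient must be non-negative")
    return loss_coefficient_W_K * (
        np.asarray(T_Atm_C, dtype=float) - np.asarray(T_surface_C, dtype=float)
    )


def predict_outlet_temperature(
    mdot_kg_s,
    T_S_in_C,
    mdot_C_kg_s,
    T_C_in_C,
    T_C_out_C,
    Q_Agi_W,
    config: MillConfig,
    T_surface_C=None,
):
    """Suspension outlet temperature from the rearranged energy balance, degC.

    ``T_surface_C`` is the chamber surface temperature for the loss term;
    it defaults to the predicted outlet temperature itself (no dedicated
    surface sensor exists), which makes the expression linear and solvable
    in closed form.  A zero suspension mass flow makes the balance singular.
    """
    mdot = np.asarray(mdot_kg_s, dtype=float)
    if np.any(mdot == 0):
        raise BalanceError("suspension mass flow is zero: balance is singular")
    coolant = (
        np.asarray(mdot_C_kg_s, dtype=float)
        * config.cp_C_J_kgK
        * (np.asarray(T_C_in_C, dtype=float) - np.asarray(T_C_out_C, dtype=float))
    )
    flow_capacity = mdot * config.cp_S_J_kgK
    alphaA = config.loss_coefficient_W_K
    T_in = np.asarray(T_S_in_C, dtype=float)
    if T_surface_C is not None or alphaA == 0.0:
        T_surf = T_in if T_surface_C is None else np.asarray(T_surface_C, dtype=float)
        q_atm = atmospheric_loss(alphaA, config.T_Atm_C, T_surf)
        return (coolant + np.asarray(Q_Agi_W, dtype=float) - q_atm) / flow_capacity + T_in
    # T_surface approximated by T_S,out itself: solve the linear equation
    #   T_out * (m cp) = coolant + Q_Agi - alphaA*(T_Atm - T_out) + T_in * (m cp)
    num = (
        coolant
        + np.asarray(Q_Agi_W, dtype=float)
        - alphaA * config.T_Atm_C
        + T_in * flow_capacity
    )
    return num / (flow_capacity - alphaA)


@dataclass
class HeatFlowBreakdown:
    """Per-sample component heat flows and the balance closure residual.

    ``residual_W = Q_S + Q_C - Q_Agi + Q_Atm``: zero when the balance closes
    under its sign conventions (suspension and coolant together carry away
    exactly the net agitator input corrected for atmospheric exchange).
    """

    t_s: np.ndarray
    Q_S_W: np.ndarray
    Q_Agi_W: np.ndarray
    Q_C_W: np.ndarray
    Q_Atm_W: np.ndarray
    residual_W: np.ndarray

    @property
    def rms_residual_W(self) -> float:
        return float(np.sqrt(np.mean(self.residual_W**2)))

    @property
    def rms_residual_relative(self) -> float:
        """RMS residual relative to the RMS agitator input."""
        scale = float(np.sqrt(np.mean(self.Q_Agi_W**2)))
        if scale == 0:
            return float("inf") if self.rms_residual_W > 0 else 0.0
        return self.rms_residual_W / scale

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t_s,
                "Q_S_W": self.Q_S_W,
                "Q_Agi_W": self.Q_Agi_W,
                "Q_C_W": self.Q_C_W,
                "Q_Atm_W": self.Q_Atm_W,
                "residual_W": self.residual_W,
            }
        )

    def summary(self) -> dict:
        return {
            "rms_residual_W": self.rms_residual_W,
            "rms_residual_relative": self.rms_residual_relative,
            "mean_Q_Agi_W": float(np.mean(self.Q_Agi_W)),
            "mean_Q_S_W": float(np.mean(self.Q_S_W)),
            "mean_Q_C_W": float(np.mean(self.Q_C_W)),
        }


def balance_residuals(
    series: SensorTimeSeries,
    config: MillConfig,
    noload: Optional[NoLoadModel] = None,
) -> HeatFlowBreakdown:
    """Evaluate the component heat flows and closure residual per sample.

    The no-load model is fitted from the run's no-load segment when not
    supplied.  All temperature and coolant channels must be present.
    """
    for ch in ("T_S_in_C", "T_S_out_C", "T_C_in_C", "T_C_out_C", "mdot_C_kg_s"):
        if not series.has_channel(ch):
            raise DataError(f"energy balance requires channel {ch}")
    if noload is None:
        noload = fit_noload(series, config)
    P = shaft_power(series.F_N, config.load_cell_radius_m, series.n_rpm / 60.0)
    P0 = np.asarray(noload.predict(series.n_rpm), dtype=float)
    from .mill import _mass_flow  # shared channel fallback logic

    mdot = _mass_flow(series, config)
    q_s = suspension_heat(mdot, config.cp_S_J_kgK, series.T_S_in_C, series.T_S_out_C)
    q_agi = agitator_heat(P, P0)
    q_c = coolant_heat(
        series.mdot_C_kg_s, config.cp_C_J_kgK, series.T_C_in_C, series.T_C_out_C
    )
    q_atm = atmospheric_loss(
        config.loss_coefficient_W_K, config.T_Atm_C, series.T_S_out_C
    )
    residual = q_s + q_c - q_agi + q_atm
    return HeatFlowBreakdown(series.t_s, q_s, q_agi, q_c, q_atm, residual)
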