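"""Empirical process-product relationship x_PCS(E_M) and batch dispersion
statistics.

The mean particle size of the milled nanosuspension correlates tightly with
the cumulative mass-specific energy.  The default functional form is a power
law, ``x = a * E_M**b`` with b < 0, fitted by least squares on the log-log
scale; an asymptotic grinding-limit variant ``x = x_lim + a * E_M**b`` is
available behind a flag.  The power law keeps the inversion (size target ->
required specific energy) closed-form, which is what places size acceptance
limits on the E_M axis of the design space.

Dispersion statistics use the sample standard deviation (n-1 denominator)
throughout; RSD = 100 * sd / mean.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit

from .errors import ExtrapolationWarning, FitError
from .io import BatchRecord


@dataclass
class SizeEnergyCorrelation:
    """Fitted size-energy law with residual diagnostics.

    ``form`` is ``power`` (x = a * E^b) or ``grinding-limit``
    (x = x_lim + a * E^b).  ``em_range`` and ``size_range`` delimit the
    fitted data; predictions outside them carry an extrapolation warning.
    ``residuals_pct`` are per-point relative residuals, 100*(pred-obs)/obs.
    """

    intercept: float  # a: nm at E_M = 1 kJ/kg
    exponent: float  # b: dimensionless, negative for size reduction
    form: str = "power"
    x_lim_nm: float = 0.0
    em_range: tuple = (0.0, float("inf"))
    size_range: tuple = (0.0, float("inf"))
    residuals_pct: np.ndarray = field(default_factory=lambda: np.array([]))
    experiment_ids: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["residuals_pct"] = np.asarray(self.residuals_pct).tolist()
        d["em_range"] = list(self.em_range)
        d["size_range"] = list(self.size_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SizeEnergyCorrelation":
        d = dict(d)
        d["residuals_pct"] = np.asarray(d.get("residuals_pct", []), dtype=float)
        d["em_range"] = tuple(d.get("em_range", (0.0, float("inf"))))
        d["size_range"] = tuple(d.get("size_range", (0.0, float("inf"))))
        return cls(**d)


def _extract(records: Sequence[BatchRecord], attr: str) -> np.ndarray:
    vals = [getattr(r, attr) for r in records]
    if any(v is None for v in vals):
        missing = [r.experiment for r, v in zip(records, vals) if v is None]
        raise FitError(f"records missing {attr}: {missing}")
    return np.asarray(vals, dtype=float)


def fit_size_energy(
    records: Sequence[BatchRecord], form: str = "power"
) -> SizeEnergyCorrelation:
    """Least-squares fit of the size-energy law on a batch table.

    Fits ln(x_PCS) on ln(E_M) for the power form.  Requires at least two
    records spanning a positive E_M range; a single distinct energy value is
    degenerate.  For the grinding-limit form the power fit seeds a bounded
    nonlinear least-squares refinement.
    """
    records = list(records)
    if len(records) < 2:
        raise FitError("need at least 2 records to fit the size-energy law")
    E = _extract(records, "E_M_kJ_kg")
    x = _extract(records, "x_PCS_nm")
    if np.any(E <= 0) or np.any(x <= 0):
        raise FitError("E_M and x_PCS must be positive for the log-log fit")
    if np.ptp(E) <= 0:
        raise FitError("degenerate fit: all records share one E_M value")

    b, ln_a = np.polyfit(np.log(E), np.log(x), 1)
    a = float(np.exp(ln_a))
    x_lim = 0.0
    if form == "grinding-limit":

        def model(e, xl, aa, bb):
            return xl + aa * e**bb

        try:
            (x_lim, a, b), _ = curve_fit(
                model,
                E,
                x,
                p0=(0.0, a, b),
                bounds=([0.0, 0.0, -5.0], [np.min(x), np.inf, 0.0]),
                maxfev=10000,
            )
        except RuntimeError as exc:  # pragma: no cover - pathological data
            raise FitError(f"grinding-limit fit did not converge: {exc}") from exc
    elif form != "power":
        raise FitError(f"unknown functional form: {form!r}")

    corr = SizeEnergyCorrelation(
        intercept=float(a),
        exponent=float(b),
        form=form,
        x_lim_nm=float(x_lim),
        em_range=(float(np.min(E)), float(np.max(E))),
        size_range=(float(np.min(x)), float(np.max(x))),
        experiment_ids=[r.experiment for r in records],
    )
    pred = predict_size(corr, E, warn_extrapolation=False)
    corr.residuals_pct = 100.0 * (pred - x) / x
    return corr


def predict_size(
    corr: SizeEnergyCorrelation, E_M_kJ_kg, warn_extrapolation: bool = True
):
    """Predicted mean particle size in nm at the given specific energy."""
    E = np.asarray(E_M_kJ_kg, dtype=float)
    scalar = E.ndim == 0
    E = np.atleast_1d(E)
    if np.any(E <= 0):
        raise ValueError("E_M must be positive")
    if warn_extrapolation and (
        np.any(E < corr.em_range[0]) or np.any(E > corr.em_range[1])
    ):
        warnings.warn(
            "evaluating size-energy correlation outside its fitted E_M range",
            ExtrapolationWarning,
            stacklevel=2,
        )
    x = corr.x_lim_nm + corr.intercept * E**corr.exponent
    return float(x[0]) if scalar else x


#: Relative margin beyond the fitted size span still accepted by
#: ``inverse_energy`` / design-space construction before erroring out.  The
#: acceptance window of the product specification may slightly exceed the
#: span of sizes realized in the campaign (extrapolation by a few percent);
#: gross extrapolation is refused.
SIZE_RANGE_MARGIN = 0.25


def inverse_energy(corr: SizeEnergyCorrelation, x_target_nm: float) -> float:
    """Specific energy (kJ/kg) at which the fitted law predicts ``x_target``.

    Closed form for the power law; bracketed root search for the
    grinding-limit form.  Targets outside the fitted size range trigger an
    extrapolation warning; targets beyond a 25% margin raise."""
    if not x_target_nm > 0:
        raise ValueError("size target must be positive")
    if corr.form == "grinding-limit" and x_target_nm <= corr.x_lim_nm:
        raise ValueError(
            f"size target {x_target_nm} nm at or below the grinding limit "
            f"{corr.x_lim_nm:.1f} nm is unreachable"
        )
    lo, hi = corr.size_range
    if not (lo * (1 - SIZE_RANGE_MARGIN) <= x_target_nm <= hi * (1 + SIZE_RANGE_MARGIN)):
        raise ValueError(
            f"size target {x_target_nm} nm too far outside fitted range "
            f"[{lo:.0f}, {hi:.0f}] nm"
        )
    if not (lo <= x_target_nm <= hi):
        warnings.warn(
            "size target outside fitted size range; extrapolating",
            ExtrapolationWarning,
            stacklevel=2,
        )
    if corr.form == "power":
        return float((x_target_nm / corr.intercept) ** (1.0 / corr.exponent))

    def f(e):
        return corr.x_lim_nm + corr.intercept * e**corr.exponent - x_target_nm

    e_lo, e_hi = corr.em_range
    # widen the bracket until it straddles the root (monotone decreasing law)
    while f(e_lo) < 0 and e_lo > 1e-6:
        e_lo /= 2.0
    while f(e_hi) > 0 and e_hi < 1e9:
        e_hi *= 2.0
    return float(brentq(f, e_lo, e_hi, xtol=1e-12, rtol=1e-12))


# ---------------------------------------------------------------------------
# Grouped dispersion statistics
# ---------------------------------------------------------------------------


@dataclass
class GroupStatistics:
    """Per-group mean / sd / RSD of a batch-table attribute."""

    key: str
    table: pd.DataFrame  # columns: group, n, mean, sd, rsd_pct

    @property
    def max_rsd_pct(self) -> float:
        return float(self.table["rsd_pct"].max())


def grouped_rsd(
    records: Sequence[BatchRecord],
    key: str,
    groups: dict,
    attr: str = "x_PCS_nm",
) -> GroupStatistics:
    """RSD of ``attr`` within explicit groups of experiments.

    ``groups`` maps a group name to the experiment ids it contains (ids as
    printed in the batch table).  ``key`` documents the grouping variable
    (constant E_M or constant N); it is metadata, the group memberships are
    taken as given.  Groups of fewer than two members are excluded from the
    RSD table.  Referencing a missing experiment id raises ``KeyError``.
    """
    by_id = {r.experiment: r for r in records}
    rows = []
    for name, ids in groups.items():
        ids = [str(i) for i in ids]
        missing = [i for i in ids if i not in by_id]
        if missing:
            raise KeyError(f"group {name!r} references unknown experiments {missing}")
        vals = np.asarray([getattr(by_id[i], attr) for i in ids], dtype=float)
        if vals.size < 2:
            continue
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1))
        rows.append(
            {
                "group": str(name),
                "n": int(vals.size),
                "mean": mean,
                "sd": sd,
                "rsd_pct": 100.0 * sd / mean,
            }
        )
    return GroupStatistics(key=key, table=pd.DataFrame(rows))


def pdi_statistics(records: Sequence[BatchRecord]):
    """Mean, sample sd and RSD (%) of the polydispersity index."""
    vals = _extract(records, "PdI")
    if vals.size < 2:
        raise FitError("need at least 2 records for PdI statistics")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))
    return mean, sd, 100.0 * sd / mean


def outlet_temperature_span(records: Sequence[BatchRecord]) -> float:
    """Span (max - min) of the average suspension outlet temperature, degC."""
    vals = _extract(records, "T_S_out_C")
    if vals.size < 2:
        raise FitError("need at least 2 records for a temperature span")
    return float(np.max(vals) - np.min(vals))
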