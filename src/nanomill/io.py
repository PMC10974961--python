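"""Data model and I/O for mill sensor runs, batch tables and equipment configuration.

The sensor schema follows the instrumentation of a recirculation-mode wet
stirred media mill: load-cell force at the agitator shaft, shaft speed,
suspension mass/volume flow, suspension inlet/outlet temperatures at the
grinding chamber, and coolant inlet/outlet temperatures with coolant mass
flow at the chamber jacket.  Interface units are the ones customary on the
plant (rpm, L/min, kJ/kg, μNm, nm); conversions to SI happen inside the
model modules.
"""

from __future__ import annotations

import dataclasses
import hashlib
import importlib.resources
import io as _stdio
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigurationError,
    DataError,
    SchemaError,
    TimeSeriesValidationError,
)

#: Canonical sensor CSV columns. ``mdot_kg_s`` and the coolant channels are
#: optional at read time (a run without jacket instrumentation is analyzable,
#: the energy balance is then skipped).
SENSOR_COLUMNS = (
    "t_s",
    "F_N",
    "n_rpm",
    "mdot_kg_s",
    "Vdot_L_min",
    "T_S_in_C",
    "T_S_out_C",
    "T_C_in_C",
    "T_C_out_C",
    "mdot_C_kg_s",
)
REQUIRED_COLUMNS = ("t_s", "F_N", "n_rpm", "Vdot_L_min", "T_S_in_C", "T_S_out_C")
OPTIONAL_COLUMNS = tuple(c for c in SENSOR_COLUMNS if c not in REQUIRED_COLUMNS)

#: Segment labels used by the run protocol: pre-run no-load measurement,
#: low-flow start plus ramp-up, then constant-flow main processing.
SEGMENT_LABELS = ("noload", "ramp", "main")

TEMPERATURE_CHANNELS = ("T_S_in_C", "T_S_out_C", "T_C_in_C", "T_C_out_C")
FLOW_CHANNELS = ("mdot_kg_s", "Vdot_L_min", "mdot_C_kg_s")


@dataclass
class Violation:
    """One structural defect found in a sensor series."""

    channel: str
    index: Optional[int]
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = f"[{self.index}]" if self.index is not None else ""
        return f"{self.channel}{where}: {self.message}"


@dataclass
class SensorTimeSeries:
    """Multichannel record of one milling run on a common time grid.

    All channels are float arrays of equal length; time is seconds since run
    start.  ``segment`` optionally labels each sample as ``noload``, ``ramp``
    or ``main``.  Missing optional channels are all-NaN arrays.
    """

    t_s: np.ndarray
    F_N: np.ndarray
    n_rpm: np.ndarray
    mdot_kg_s: np.ndarray
    Vdot_L_min: np.ndarray
    T_S_in_C: np.ndarray
    T_S_out_C: np.ndarray
    T_C_in_C: np.ndarray
    T_C_out_C: np.ndarray
    mdot_C_kg_s: np.ndarray
    segment: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = None
        for name in SENSOR_COLUMNS:
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.ndim != 1:
                raise SchemaError(f"channel {name} must be one-dimensional")
            if n is None:
                n = arr.size
            elif arr.size != n:
                raise SchemaError(
                    f"channel {name} has length {arr.size}, expected {n}"
                )
        if self.segment is not None:
            seg = np.asarray(self.segment, dtype=object)
            if seg.size != n:
                raise SchemaError("segment labels must match channel length")
            self.segment = seg

    def __len__(self) -> int:
        return int(self.t_s.size)

    def copy(self) -> "SensorTimeSeries":
        return SensorTimeSeries(
            **{c: getattr(self, c).copy() for c in SENSOR_COLUMNS},
            segment=None if self.segment is None else self.segment.copy(),
            metadata=dict(self.metadata),
        )

    def segment_mask(self, *labels: str) -> np.ndarray:
        """Boolean mask of samples whose segment label is in ``labels``."""
        if self.segment is None:
            return np.ones(len(self), dtype=bool)
        return np.isin(self.segment, labels)

    def has_channel(self, name: str) -> bool:
        """Whether the channel carries at least one finite value."""
        return bool(np.isfinite(getattr(self, name)).any())

    def to_frame(self) -> pd.DataFrame:
        data = {c: getattr(self, c) for c in SENSOR_COLUMNS}
        if self.segment is not None:
            data["segment"] = self.segment
        return pd.DataFrame(data)


def validate_run(series: SensorTimeSeries) -> list[Violation]:
    """Report structural violations of a sensor series without raising.

    Checks: length >= 2, strictly increasing time, non-negative flows,
    plausible temperatures (-20 ... 150 degC).  NaN entries in optional
    channels are accepted (channel absent); NaN in a required channel is a
    violation.  The input is never mutated.
    """
    violations: list[Violation] = []
    n = len(series)
    if n < 2:
        violations.append(Violation("t_s", None, "too short: need at least 2 samples"))
        return violations

    dt = np.diff(series.t_s)
    bad = np.where(dt <= 0)[0]
    if bad.size:
        violations.append(
            Violation("t_s", int(bad[0] + 1), "time not strictly increasing")
        )

    for name in REQUIRED_COLUMNS:
        arr = getattr(series, name)
        nan = np.where(~np.isfinite(arr))[0]
        if nan.size:
            violations.append(Violation(name, int(nan[0]), "non-finite value"))

    for name in FLOW_CHANNELS:
        arr = getattr(series, name)
        neg = np.where(np.isfinite(arr) & (arr < 0))[0]
        if neg.size:
            violations.append(Violation(name, int(neg[0]), "negative flow"))

    for name in TEMPERATURE_CHANNELS:
        arr = getattr(series, name)
        out = np.where(np.isfinite(arr) & ((arr < -20.0) | (arr > 150.0)))[0]
        if out.size:
            violations.append(
                Violation(name, int(out[0]), "temperature outside -20...150 degC")
            )

    if series.segment is not None:
        unknown = np.where(~np.isin(series.segment, SEGMENT_LABELS))[0]
        if unknown.size:
            violations.append(
                Violation("segment", int(unknown[0]), "unknown segment label")
            )
    return violations


def read_timeseries(path, schema: Optional[dict] = None) -> SensorTimeSeries:
    """Read a sensor CSV (comma-separated, dot decimal, header row, UTF-8).

    ``schema`` optionally maps file column names onto the canonical names in
    :data:`SENSOR_COLUMNS`.  Missing required columns raise
    :class:`SchemaError` naming the column; a structurally invalid series
    raises :class:`TimeSeriesValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns=schema)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col}")
    if df.shape[0] == 0:
        raise SchemaError(f"empty sensor file: {path}")
    channels = {}
    for col in SENSOR_COLUMNS:
        if col in df.columns:
            channels[col] = df[col].to_numpy(dtype=float)
        else:
            channels[col] = np.full(df.shape[0], np.nan)
    segment = None
    if "segment" in df.columns:
        segment = df["segment"].to_numpy(dtype=object)
    series = SensorTimeSeries(**channels, segment=segment)
    violations = validate_run(series)
    if violations:
        raise TimeSeriesValidationError(violations)
    return series


def write_timeseries(series: SensorTimeSeries, path) -> None:
    """Write a sensor series as canonical CSV (round-trips to 1e-9 relative)."""
    df = series.to_frame()
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Batch records (one row of the reference batch-table schema)
# ---------------------------------------------------------------------------

#: Column order of the batch-table TSV interchange format.
BATCH_COLUMNS = (
    "experiment",
    "x90_3_um",
    "M_kg",
    "n_rpm",
    "Vdot_L_min",
    "T_C_in_C",
    "T_S_out_C",
    "E_M_kJ_kg",
    "SE_uNm",
    "N",
    "x_PCS_nm",
    "PdI",
)


@dataclass
class BatchRecord:
    """One manufactured batch: set parameters, resulting cumulative process
    parameters and (optionally) the measured quality attributes.

    Units: x90_3 input drug size in um, batch mass in kg, shaft speed in rpm,
    suspension volume flow in L/min, temperatures in degC, mass-specific
    energy in kJ/kg, average stress energy in uNm, turnover cycles
    dimensionless, mean particle size in nm, PdI dimensionless.
    """

    experiment: str
    x90_3_um: Optional[float]
    M_kg: float
    n_rpm: float
    Vdot_L_min: float
    T_C_in_C: float
    T_S_out_C: float
    E_M_kJ_kg: float
    SE_uNm: float
    N: float
    x_PCS_nm: Optional[float] = None
    PdI: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("M_kg", "n_rpm", "Vdot_L_min", "E_M_kJ_kg", "SE_uNm", "N"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise DataError(f"batch {self.experiment}: {name} must be positive")
        if self.PdI is not None and not (0.0 <= self.PdI <= 1.0):
            raise DataError(f"batch {self.experiment}: PdI outside [0, 1]")
        if self.x_PCS_nm is not None and not self.x_PCS_nm > 0:
            raise DataError(f"batch {self.experiment}: x_PCS must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def records_to_frame(records) -> pd.DataFrame:
    """Batch records as a DataFrame in canonical column order."""
    return pd.DataFrame([r.to_dict() for r in records], columns=list(BATCH_COLUMNS))


def frame_to_records(df: pd.DataFrame) -> list[BatchRecord]:
    missing = [c for c in BATCH_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing batch-table columns: {', '.join(missing)}")
    df = df.copy()
    # keep ids as strings before row-wise access upcasts mixed dtypes
    df["experiment"] = df["experiment"].astype(str)
    records = []
    for _, row in df.iterrows():
        d = {c: row[c] for c in BATCH_COLUMNS}
        d["experiment"] = str(d["experiment"])
        for k, v in list(d.items()):
            if k != "experiment" and pd.isna(v):
                d[k] = None
        records.append(BatchRecord(**d))
    return records


def read_batch_table(path) -> list[BatchRecord]:
    """Read a batch table (TSV, canonical columns)."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    return frame_to_records(pd.read_csv(path, sep="\t"))


def write_batch_table(records, path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


#: SHA-256 of the packaged 22-experiment reference batch table.
REFERENCE_TABLE_SHA256 = (
    "d2a2df2d85469bf793fdd4df92d7fdd8185fe8e4cb1fb692fe0ab0fd26938af3"
)


def load_reference_table() -> list[BatchRecord]:
    """Load the packaged 22-experiment commercial-scale reference table.

    Returns exactly 22 records in printed row order.  The fixture is
    checksummed; corruption raises :class:`DataError`.
    """
    resource = importlib.resources.files("nanomill.data") / "reference_batches.tsv"
    raw = resource.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != REFERENCE_TABLE_SHA256:
        raise DataError(
            "reference batch table failed checksum verification "
            f"(got {digest[:12]}...)"
        )
    df = pd.read_csv(_stdio.BytesIO(raw), sep="\t")
    records = frame_to_records(df)
    if len(records) != 22:
        raise DataError(f"reference table has {len(records)} rows, expected 22")
    return records


# ---------------------------------------------------------------------------
# Equipment / physical-property configuration
# ---------------------------------------------------------------------------


@dataclass
class MillConfig:
    """Equipment constants and physical-property defaults of the mill.

    The average stress energy is evaluated as ``SE = kappa * mean(v_t^2)``
    where ``v_t`` is the agitator tip speed.  ``kappa`` stands in for
    ``rho_GM * d_GM^3`` (grinding-media density times bead diameter cubed)
    with the tip-speed geometry folded in; by default it is calibrated from a
    reference operating point (``reference_SE_uNm`` at
    ``reference_speed_rpm``), because bead properties and rotor diameter are
    proprietary equipment data.  When ``rho_GM_kg_m3`` and ``d_GM_m`` are
    supplied they take precedence over the calibration.

    ``load_cell_radius_m`` and ``rotor_diameter_m`` are representative
    defaults for a production-scale mill; both cancel out of every calibrated
    ratio the models report.
    """

    load_cell_radius_m: float = 0.2
    rotor_diameter_m: float = 0.28
    reference_speed_rpm: Optional[float] = 1050.0
    reference_SE_uNm: Optional[float] = 0.88
    cp_S_J_kgK: float = 3900.0
    cp_C_J_kgK: float = 4180.0
    rho_S_kg_L: float = 1.1
    loss_coefficient_W_K: float = 0.0
    T_Atm_C: float = 20.0
    rho_GM_kg_m3: Optional[float] = None
    d_GM_m: Optional[float] = None
    N_GM: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.load_cell_radius_m > 0:
            raise ConfigurationError("load_cell_radius_m must be positive")
        if not self.rotor_diameter_m > 0:
            raise ConfigurationError("rotor_diameter_m must be positive")
        if not (self.cp_S_J_kgK > 0 and self.cp_C_J_kgK > 0):
            raise ConfigurationError("heat capacities must be positive")
        if not (0.9 <= self.rho_S_kg_L <= 1.5):
            raise ConfigurationError("rho_S_kg_L outside plausible 0.9...1.5 kg/L")
        if self.loss_coefficient_W_K < 0:
            raise ConfigurationError("loss_coefficient_W_K must be >= 0")

    def tip_speed_m_s(self, n_rpm) -> np.ndarray:
        """Agitator tip speed v_t = pi * D * n for shaft speed in rpm."""
        return np.pi * self.rotor_diameter_m * np.asarray(n_rpm, dtype=float) / 60.0

    def stress_energy_constant(self) -> float:
        """kappa in uNm per (m/s)^2 such that SE = kappa * mean(v_t^2)."""
        if self.rho_GM_kg_m3 is not None and self.d_GM_m is not None:
            # SE = rho_GM * d_GM^3 * v_t^2 -> J, reported in uNm (1 J = 1e6 uNm)
            return self.rho_GM_kg_m3 * self.d_GM_m**3 * 1e6
        if self.reference_speed_rpm is not None and self.reference_SE_uNm is not None:
            vref = float(self.tip_speed_m_s(self.reference_speed_rpm))
            return self.reference_SE_uNm / vref**2
        raise ConfigurationError(
            "stress-energy constant requires either grinding-media descriptors "
            "(rho_GM_kg_m3, d_GM_m) or a calibration point "
            "(reference_speed_rpm, reference_SE_uNm)"
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MillConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "MillConfig":
        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        if not isinstance(payload, dict):
            raise ConfigurationError("config file must contain a mapping")
        return cls.from_dict(payload)

    def hash(self) -> str:
        """Stable hash of the configuration, for output manifests."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
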