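"""Control strategy encoding and batch disposition.

The control strategy assigns every material attribute and process parameter
a criticality designation (CMA / CPP / CQA or explicitly non-critical), a
control measure (certificate of analysis, process control system, batch
record, in-process control) and -- where numeric -- an acceptable range.
The two CPPs, mass-specific energy and turnover cycles, are controlled
jointly through the design space rather than through independent ranges;
the CQA mean particle size is checked by the in-process control window.

Batch disposition: ``reject`` on any failed check, ``review`` when only
warnings exist (e.g. unchecked parameters), ``accept`` otherwise.  All range
checks are boundary-inclusive.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from .designspace import DesignSpace, contains
from .errors import ConfigurationError
from .io import BatchRecord

#: The printed control-strategy table caps the shaft speed at 1215 rpm while
#: the experimental-design table allows 1225 rpm; the discrepancy is most
#: likely typographical.  The default follows the control-strategy value and
#: warns loudly when a batch falls in between; the alternative bound can be
#: selected explicitly.
SPEED_UPPER_DEFAULT_RPM = 1215.0
SPEED_UPPER_ALTERNATE_RPM = 1225.0


@dataclass
class ControlEntry:
    """One parameter of the control strategy."""

    parameter: str
    category: str
    criticality: str
    measures: list = field(default_factory=list)
    field_name: Optional[str] = None  # BatchRecord attribute carrying the value
    lo: Optional[float] = None
    hi: Optional[float] = None
    units: Optional[str] = None
    design_space: bool = False

    @property
    def ranged(self) -> bool:
        return self.lo is not None or self.hi is not None

    def check(self, value: Optional[float]) -> str:
        if not self.ranged or value is None or not np.isfinite(value):
            return "not-checked"
        if self.lo is not None and value < self.lo:
            return "fail"
        if self.hi is not None and value > self.hi:
            return "fail"
        return "pass"


@dataclass
class ControlStrategySpec:
    """Complete control strategy: one entry per attribute/parameter."""

    entries: list

    def __post_init__(self) -> None:
        cpps = {e.parameter for e in self.entries if e.criticality == "CPP"}
        if cpps != {"mass specific energy", "number of turnover cycles"}:
            raise ConfigurationError(
                "CPP entries must be exactly mass specific energy and "
                f"number of turnover cycles, got {sorted(cpps)}"
            )
        cqas = {e.parameter for e in self.entries if e.criticality == "CQA"}
        if cqas != {"mean particle size"}:
            raise ConfigurationError(
                f"CQA entry must be exactly mean particle size, got {sorted(cqas)}"
            )
        for e in self.entries:
            if e.lo is not None and e.hi is not None and not e.lo <= e.hi:
                raise ConfigurationError(f"entry {e.parameter!r} has lo > hi")

    def entry(self, parameter: str) -> ControlEntry:
        for e in self.entries:
            if e.parameter == parameter:
                return e
        raise KeyError(parameter)

    @classmethod
    def from_yaml(cls, path_or_payload) -> "ControlStrategySpec":
        if isinstance(path_or_payload, dict):
            payload = path_or_payload
        else:
            with open(path_or_payload, "r", encoding="utf-8") as fh:
                payload = yaml.safe_load(fh)
        entries = []
        for raw in payload["entries"]:
            raw = dict(raw)
            field_name = raw.pop("field", None)
            entries.append(ControlEntry(field_name=field_name, **raw))
        return cls(entries=entries)


def default_strategy(
    speed_upper_rpm: float = SPEED_UPPER_DEFAULT_RPM,
) -> ControlStrategySpec:
    """The packaged default control strategy.

    ``speed_upper_rpm`` switches the agitator-speed upper bound between the
    two values printed in the source tables (1215 default, 1225 alternate).
    """
    resource = importlib.resources.files("nanomill.data") / "control_strategy.yaml"
    payload = yaml.safe_load(resource.read_text(encoding="utf-8"))
    spec = ControlStrategySpec.from_yaml(payload)
    spec.entry("agitator shaft speed").hi = float(speed_upper_rpm)
    return spec


@dataclass
class ParameterVerdict:
    parameter: str
    value: Optional[float]
    lo: Optional[float]
    hi: Optional[float]
    status: str  # pass | fail | not-checked

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "value": self.value,
            "lo": self.lo,
            "hi": self.hi,
            "status": self.status,
        }


@dataclass
class EvaluationReport:
    """Disposition of one batch against the control strategy + design space."""

    experiment: str
    parameter_verdicts: list
    design_space_status: str  # pass | fail | not-checked
    ipc_status: str  # pass | fail | not-checked
    warnings: list
    disposition: str  # accept | reject | review

    def to_dict(self) -> dict:
        return {
            "experiment": self.experiment,
            "parameters": [v.to_dict() for v in self.parameter_verdicts],
            "design_space": self.design_space_status,
            "ipc": self.ipc_status,
            "warnings": list(self.warnings),
            "disposition": self.disposition,
        }

    def to_text(self) -> str:
        lines = [f"batch {self.experiment}: {self.disposition.upper()}"]
        for v in self.parameter_verdicts:
            rng = f"[{v.lo}, {v.hi}]".replace("None", "-")
            lines.append(f"  {v.parameter:55s} {str(v.value):>10s} {rng:>16s} {v.status}")
        lines.append(f"  design space (E_M, N): {self.design_space_status}")
        lines.append(f"  IPC mean particle size: {self.ipc_status}")
        for w in self.warnings:
            lines.append(f"  warning: {w}")
        return "\n".join(lines)


def evaluate_batch(
    record: BatchRecord, spec: ControlStrategySpec, space: DesignSpace
) -> EvaluationReport:
    """Evaluate one batch record against every control-strategy entry.

    Ranged entries are checked boundary-inclusively against the record
    field; a missing value yields a ``not-checked`` verdict plus a warning,
    never a silent pass.  The CPPs are checked jointly via design-space
    membership, the CQA via the in-process-control size window.  Evaluation
    is pure: identical inputs produce identical reports.
    """
    verdicts: list[ParameterVerdict] = []
    warnings_list: list[str] = []
    any_fail = False

    for entry in spec.entries:
        if entry.design_space or entry.criticality == "CQA":
            continue  # handled separately below
        value = None
        if entry.field_name is not None:
            value = getattr(record, entry.field_name, None)
            if value is not None and not np.isfinite(value):
                value = None
        status = entry.check(value)
        if entry.ranged:
            verdicts.append(
                ParameterVerdict(entry.parameter, value, entry.lo, entry.hi, status)
            )
            if status == "fail":
                any_fail = True
            elif status == "not-checked":
                warnings_list.append(f"{entry.parameter}: no value supplied")
        else:
            verdicts.append(ParameterVerdict(entry.parameter, value, None, None, "not-checked"))

    speed_entry = spec.entry("agitator shaft speed")
    if (
        record.n_rpm is not None
        and speed_entry.hi is not None
        and speed_entry.hi < record.n_rpm <= SPEED_UPPER_ALTERNATE_RPM
    ):
        warnings_list.append(
            f"agitator speed {record.n_rpm:g} rpm exceeds the control-strategy "
            f"bound {speed_entry.hi:g} rpm but is within the alternate printed "
            f"bound {SPEED_UPPER_ALTERNATE_RPM:g} rpm"
        )

    # CPPs: joint membership in the design space
    if record.E_M_kJ_kg is None or record.N is None:
        ds_status = "not-checked"
        warnings_list.append("design space: E_M or N missing")
    else:
        ds_status = "pass" if contains(space, record.E_M_kJ_kg, record.N) else "fail"
    if ds_status == "fail":
        any_fail = True

    # CQA: in-process-control size window
    cqa = spec.entry("mean particle size")
    ipc_status = cqa.check(record.x_PCS_nm)
    if ipc_status == "fail":
        any_fail = True
    elif ipc_status == "not-checked":
        warnings_list.append("IPC: mean particle size not measured")

    if any_fail:
        disposition = "reject"
    elif warnings_list:
        disposition = "review"
    else:
        disposition = "accept"
    return EvaluationReport(
        experiment=record.experiment,
        parameter_verdicts=verdicts,
        design_space_status=ds_status,
        ipc_status=ipc_status,
        warnings=warnings_list,
        disposition=disposition,
    )


def evaluate_campaign(
    records: Sequence[BatchRecord], spec: ControlStrategySpec, space: DesignSpace
):
    """Evaluate a batch table; returns (reports, summary).

    The summary counts dispositions and IPC passes across the campaign.
    """
    reports = [evaluate_batch(r, spec, space) for r in records]
    summary = {
        "n": len(reports),
        "accept": sum(r.disposition == "accept" for r in reports),
        "reject": sum(r.disposition == "reject" for r in reports),
        "review": sum(r.disposition == "review" for r in reports),
        "ipc_pass": sum(r.ipc_status == "pass" for r in reports),
        "in_design_space": sum(r.design_space_status == "pass" for r in reports),
    }
    return reports, summary
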