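#!/usr/bin/env python
"""Evaluate every reference batch against the control strategy.

Applies the full control strategy (material/equipment/process ranges, joint
CPP check via the design space, in-process size control) to the 22 reference
batches and tabulates dispositions.  Writes results/dispositions.csv and
results/campaign_summary.json.
"""

import json
from pathlib import Path

import pandas as pd

import nanomill as nm

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = nm.load_reference_table()
    spec = nm.default_strategy()
    space = nm.default_design_space(records)
    reports, summary = nm.evaluate_campaign(records, spec, space)

    rows = []
    for report in reports:
        fails = [v.parameter for v in report.parameter_verdicts if v.status == "fail"]
        if report.design_space_status == "fail":
            fails.append("design space (E_M, N)")
        if report.ipc_status == "fail":
            fails.append("IPC mean particle size")
        rows.append(
            {
                "experiment": report.experiment,
                "disposition": report.disposition,
                "design_space": report.design_space_status,
                "ipc": report.ipc_status,
                "failed_checks": "; ".join(fails),
                "n_warnings": len(report.warnings),
            }
        )
    df = pd.DataFrame(rows)

    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "dispositions.csv", index=False)
    (OUT / "campaign_summary.json").write_text(json.dumps(summary, indent=2))

    print(df.to_string(index=False))
    print(
        f"\n{summary['accept']} accepted, {summary['reject']} rejected, "
        f"{summary['review']} for review; {summary['ipc_pass']}/22 pass the IPC window"
    )


if __name__ == "__main__":
    main()
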