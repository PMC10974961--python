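#!/usr/bin/env python
"""Construct the (E_M, N) design space for the 120-180 nm acceptance window.

Builds the default six-vertex polygon (E_M extent from the inverted size law,
N extent from the demonstrated turnover span, corners beveled to the
experimental coverage), classifies every reference batch against it, and
interpolates the size surface.  Writes results/design_space.json,
results/design_space_membership.csv and results/size_surface.csv.
"""

import json
from pathlib import Path

import nanomill as nm

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = nm.load_reference_table()
    space = nm.default_design_space(records)
    membership = nm.classify_batches(space, records)
    surface = nm.build_size_surface(records)

    OUT.mkdir(exist_ok=True)
    (OUT / "design_space.json").write_text(json.dumps(space.to_dict(), indent=2))
    membership.to_csv(OUT / "design_space_membership.csv", index=False)
    surface.to_frame().to_csv(OUT / "size_surface.csv", index=False, float_format="%.5g")

    print("design-space vertices (E_M kJ/kg, N):")
    for e, n in space.vertices:
        print(f"  ({e:7.0f}, {n:5.1f})")
    in_window = int(membership["in_window"].sum())
    consistent = membership.loc[membership["in_window"], "in_space"].all()
    print(f"{in_window}/22 batches inside the size window")
    print(f"all in-window batches inside the polygon: {consistent}")
    outliers = membership[~membership["in_window"]]
    print("outside the window:", ", ".join(
        f"run {r.experiment} ({r.x_PCS_nm:.0f} nm)" for r in outliers.itertuples()
    ))


if __name__ == "__main__":
    main()
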