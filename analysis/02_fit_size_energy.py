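#!/usr/bin/env python
"""Fit the size-energy power law x_PCS = a * E_M^b on the reference table.

The exponent b < 0 quantifies how mean particle size shrinks with specific
energy; the inverse law places size acceptance limits on the E_M axis.
Writes results/correlation.json and results/correlation_residuals.csv.
"""

import json
from pathlib import Path

import pandas as pd

import nanomill as nm

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = nm.load_reference_table()
    corr = nm.fit_size_energy(records)

    residuals = pd.DataFrame(
        {
            "experiment": [r.experiment for r in records],
            "E_M_kJ_kg": [r.E_M_kJ_kg for r in records],
            "x_PCS_nm": [r.x_PCS_nm for r in records],
            "predicted_nm": [nm.predict_size(corr, r.E_M_kJ_kg) for r in records],
            "residual_pct": corr.residuals_pct,
        }
    )

    import warnings

    from nanomill.errors import ExtrapolationWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ExtrapolationWarning)
        e_180 = nm.inverse_energy(corr, 180.0)
        e_120 = nm.inverse_energy(corr, 120.0)

    OUT.mkdir(exist_ok=True)
    (OUT / "correlation.json").write_text(json.dumps(corr.to_dict(), indent=2))
    residuals.to_csv(OUT / "correlation_residuals.csv", index=False, float_format="%.4f")

    print(f"x_PCS = {corr.intercept:.1f} * E_M^{corr.exponent:.4f} nm")
    print(
        f"residuals: max |{residuals.residual_pct.abs().max():.2f}|%, "
        f"rms {((residuals.residual_pct**2).mean())**0.5:.2f}%"
    )
    print(f"energy window for 120-180 nm: {e_180:.0f} ... {e_120:.0f} kJ/kg")


if __name__ == "__main__":
    main()
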