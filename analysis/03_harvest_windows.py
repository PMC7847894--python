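#!/usr/bin/env python
"""Harvest windows from quadratic response surfaces.

Part A reproduces the reference result: for each cultivar's published
quadratic surface, locate the harvest-date quality peak and the
tolerance band (one reported standard error) around it — the number of
days harvest can slip before predicted quality drops by more than the
tolerance.

Part B fits the same model family to the synthetic trial (full
quadratic, so the peak is always interior when the curvature is
negative) and computes windows at the pipeline's default tolerance,
demonstrating the estimation path on data with known ground truth.

Writes results/windows_reference.csv and results/windows_fitted.csv.
"""

import subprocess
import sys
from pathlib import Path

import pandas as pd

from edamame.reference import REFERENCE_SURFACES, REFERENCE_TOLERANCES
from edamame.response_surface import ResponseSurfaceError, fit_surface, harvest_window

ROOT = Path(__file__).resolve().parents[1]
SCORED = ROOT / "results" / "scored.csv"
TOLERANCE_FITTED = 0.02


def main() -> None:
    rows = []
    for cultivar, model in REFERENCE_SURFACES.items():
        tol = REFERENCE_TOLERANCES[cultivar]
        w = harvest_window(model, tol, planting_doy=166.0)
        rows.append(
            {"cultivar": cultivar, "tolerance": tol,
             "peak_harvest_doy": round(w.peak_harvest_doy, 2),
             "width_days": round(w.width_days, 2),
             "width_days_rounded": w.width_days_rounded}
        )
    ref = pd.DataFrame(rows)
    ref.to_csv(ROOT / "results" / "windows_reference.csv", index=False)
    print("reference surfaces — harvest windows at reported one-SE tolerance:")
    print(ref.to_string(index=False))
    print("\nthe early indeterminate cultivar holds quality longest (27 d);")
    print("the MG5 determinate loses it fastest (18 d).")

    if not SCORED.exists():
        subprocess.run([sys.executable, str(ROOT / "analysis" / "02_score_quality.py")],
                       check=True)
    scored = pd.read_csv(SCORED)
    rows = []
    for cultivar, sub in scored.groupby("cultivar"):
        model = fit_surface(sub, selection="full")
        row = {"cultivar": cultivar,
               "terms": "+".join(model.included_terms),
               "beta_hd2": model.beta_hd2, "adj_r2": round(model.adj_r2, 3)}
        try:
            w = harvest_window(model, TOLERANCE_FITTED,
                               planting_doy=float(sub["planting_doy"].median()))
            row.update(peak_harvest_doy=round(w.peak_harvest_doy, 1),
                       width_days=round(w.width_days, 1))
        except ResponseSurfaceError as exc:
            row.update(peak_harvest_doy=None, width_days=None)
            print(f"note: {cultivar}: {exc}")
        rows.append(row)
    fitted = pd.DataFrame(rows)
    fitted.to_csv(ROOT / "results" / "windows_fitted.csv", index=False)
    print(f"\nsurfaces fitted to the synthetic trial (tolerance {TOLERANCE_FITTED}):")
    print(fitted.to_string(index=False))


if __name__ == "__main__":
    main()
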