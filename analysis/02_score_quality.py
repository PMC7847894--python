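#!/usr/bin/env python
"""Score the Edamame Harvest Quality Index for every plot-harvest record
of the simulated trial.

Derives IGC and hue from the raw colorimeter a*/b* readings, normalizes
hundred-pod weight by its per-(cultivar, planting date, environment)
maximum, and writes results/scored.csv.  Rows where the index is
undefined (hue at or beyond the 120-degree anchor) are dropped and
reported.
"""

import subprocess
import sys
from pathlib import Path

import pandas as pd

from edamame.io import read_quality_csv
from edamame.quality_index import score_dataset

ROOT = Path(__file__).resolve().parents[1]
TRIAL = ROOT / "results" / "trial" / "quality.csv"
OUT = ROOT / "results" / "scored.csv"


def main() -> None:
    if not TRIAL.exists():
        subprocess.run([sys.executable, str(ROOT / "analysis" / "01_simulate_trial.py")],
                       check=True)
    records = read_quality_csv(TRIAL)
    scored, report = score_dataset(records, clamp_policy="reject")
    scored.to_csv(OUT, index=False)

    print(f"scored {report.n_scored}/{report.n_input} records "
          f"({report.n_dropped} dropped: index undefined)")
    summary = (
        scored.groupby(["cultivar", "planting_doy"])["ehqi"]
        .agg(["mean", "max"])
        .round(3)
    )
    print("\nEHQI by cultivar x planting DOY:")
    print(summary.to_string())
    print("\nquality peaks early in the harvest sequence: green color fades")
    print("monotonically while pod weight plateaus, so the color product in")
    print("the denominator dominates late harvests.")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
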