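"""Sensitivity of inter-observer agreement to the seed-click jitter
magnitude.

Sweeps the observer jitter from 0 to 8 mm on a reduced cohort and records
the mean inter-observer ICC per segmentation method.  At zero jitter both
observers are identical and every ICC is exactly 1; agreement under the
gradient-edge method degrades first as jitter grows, because its ray
casting starts from the observer's click, whereas the threshold methods
depend on the click only through the search region.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from pettex import StudyConfig, run_study

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--n-patients", type=int, default=12)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

rows = []
for jitter in (0.0, 2.0, 4.0, 6.0, 8.0):
    report = run_study(StudyConfig(n_patients=args.n_patients, seed=args.seed,
                                   jitter_mm=jitter, small_fraction=0.0,
                                   size_range_ml=(8.0, 40.0)))
    for method in ("fixed40", "adaptive", "gradient"):
        iccs = [r.icc for r in report.reproducibility
                if r.method == method and np.isfinite(r.icc)]
        rows.append({"jitter_mm": jitter, "method": method,
                     "mean_icc": round(float(np.mean(iccs)), 4),
                     "min_icc": round(float(np.min(iccs)), 4)})

df = pd.DataFrame(rows)
df.to_csv(args.out / "jitter_sensitivity.csv", index=False)
print(df.pivot(index="jitter_mm", columns="method", values="mean_icc"))
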