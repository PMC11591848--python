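#!/usr/bin/env python
"""Replicate-level check of the self-assessment accuracy asymmetry.

Across 200 replicate studies of the default design, computes each
group's claim-good accuracy (share of claim-good participants scoring
at least 7) and the fraction of replicates in which musicians are more
accurate.  Writes results/metacompetence.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from corsistudy import cohort, io
from corsistudy.stats import exclude_unassessable

SEED = 717171
REPLICATES = 200


def main() -> None:
    rows = []
    for i in range(REPLICATES):
        d = exclude_unassessable(
            cohort.simulate_study(cohort.default_spec(SEED + i)).data
        )
        acc = {}
        for group, sub in d.groupby("group"):
            cg = sub[sub.self_assessment == "good"]
            acc[group] = np.nan if cg.empty else (cg.final_score >= 7.0).mean()
        rows.append({"replicate": i, "musician_accuracy": acc["musician"],
                     "non_musician_accuracy": acc["non_musician"]})
    table = pd.DataFrame(rows)
    wins = (table.musician_accuracy > table.non_musician_accuracy).mean()
    io._write_csv(table.round(4), Path("results/metacompetence.csv"), SEED, "")
    print(f"{REPLICATES} replicate studies (seed {SEED}):")
    print(f"  mean claim-good accuracy: musicians "
          f"{table.musician_accuracy.mean():.2f}, non-musicians "
          f"{table.non_musician_accuracy.mean():.2f}")
    print(f"  musicians more accurate in {wins:.1%} of replicates")


if __name__ == "__main__":
    main()
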