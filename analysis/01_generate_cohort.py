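#!/usr/bin/env python
"""Generate the default synthetic cohort and summarize its structure.

Draws the 918-record heart-disease-like cohort (55%/45% class balance,
benchmark continuous marginals, Age/MaxHR negative and Age/Oldpeak positive
correlations), writes it to results/cohort.csv, and prints the summary
statistics next to their targets so the calibration can be eyeballed.
"""

import sys
from pathlib import Path

import numpy as np

from qheart.cohort import (
    CONTINUOUS_FEATURES,
    CohortSpec,
    generate_cohort,
    split_train_test,
    write_cohort_csv,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 2025
OUT = Path("results")


def main() -> None:
    spec = CohortSpec()
    table = generate_cohort(spec, seed=SEED)
    OUT.mkdir(exist_ok=True)
    write_cohort_csv(table, OUT / "cohort.csv")

    print(f"cohort: {len(table)} records, seed {SEED}")
    print(f"prevalence: {table.HeartDisease.mean():.3f} (target "
          f"{spec.target_prevalence})")
    print(f"{'feature':<12} {'mean':>8} {'target':>8} {'sd':>7} {'target':>7}")
    for name in CONTINUOUS_FEATURES:
        m = spec.continuous_marginals[name]
        print(f"{name:<12} {table[name].mean():8.2f} {m.mean:8.2f} "
              f"{table[name].std():7.2f} {m.sd:7.2f}")
    print(f"corr(Age, MaxHR)   = {np.corrcoef(table.Age, table.MaxHR)[0,1]:+.3f}"
          " (negative expected)")
    print(f"corr(Age, Oldpeak) = {np.corrcoef(table.Age, table.Oldpeak)[0,1]:+.3f}"
          " (positive expected)")
    tr, te = split_train_test(table, 0.7, seed=SEED)
    print(f"70/30 split: {tr.size} train / {te.size} test")
    print(f"wrote {OUT / 'cohort.csv'}")


if __name__ == "__main__":
    main()
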