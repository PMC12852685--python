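#!/usr/bin/env python
"""Desk-scale sample-complexity (learning-curve) sweep.

Trains a reduced roster (perceptron, the 3x52 reference network, and angle
QNNs at 1 and 4 layers) on 10%, 50% and 100% of the training partition with
3 repeats per cell, keeping the test partition fixed.  The full roster and
fraction set of the protocol are available through the `qheart
sample-complexity` command.  Writes results/sample_complexity/.
"""

import sys
import time
from pathlib import Path

from qheart.classical import NNConfig, NNTrainConfig, reference_best_nn
from qheart.experiments import ModelSpec, records_to_frame, sample_complexity_study
from qheart.vqc import AnsatzConfig, QTrainConfig

sys.path.insert(0, str(Path(__file__).parent))
from _data import load_default_data  # noqa: E402

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 2025
OUT = Path("results/sample_complexity")


def main() -> None:
    data = load_default_data(SEED)
    roster = [
        ModelSpec(kind="nn", nn=NNConfig()),
        ModelSpec(kind="nn", nn=reference_best_nn()),
        ModelSpec(kind="qnn", qnn=AnsatzConfig(n_qubits=11, layers=1)),
        ModelSpec(kind="qnn", qnn=AnsatzConfig(n_qubits=11, layers=4)),
    ]
    t0 = time.time()
    report, ledger = sample_complexity_study(
        data, architectures=roster, fractions=(0.1, 0.5, 1.0), repeats=3,
        seed=SEED,
        qtcfg=QTrainConfig(max_epochs=200, stop_patience=50, lr_patience=25,
                           eval_every=1000),
        ntcfg=NNTrainConfig(max_epochs=800, stop_patience=200, lr_patience=80),
    )
    OUT.mkdir(parents=True, exist_ok=True)
    report.to_csv(OUT / "learning_curves.csv", index=False)
    records_to_frame(ledger).to_csv(OUT / "runs.csv", index=False)
    print(report.to_string(index=False,
                           float_format=lambda v: f"{v:.4f}"))
    print(f"done in {time.time()-t0:.0f}s -> {OUT}/")


if __name__ == "__main__":
    main()
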