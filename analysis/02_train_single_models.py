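#!/usr/bin/env python
"""Train one quantum and one classical model on the default cohort.

Desk-scale single runs of the 11-qubit angle-encoded VQC (2 layers) and the
reference 3x52 feedforward network, with training histories written to
results/histories/.  Reads results/cohort.csv if 01_generate_cohort.py has
been run, otherwise generates the cohort in memory.
"""

import sys
import time
from pathlib import Path

import pandas as pd

from qheart.classical import NNTrainConfig, nn_accuracy, reference_best_nn, train_nn
from qheart.cohort import CohortSpec, encode_dataset, generate_cohort, read_cohort_csv
from qheart.vqc import AnsatzConfig, QTrainConfig, evaluate_accuracy, train_vqc

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 2025
OUT = Path("results/histories")


def load_data():
    spec = CohortSpec()
    path = Path("results/cohort.csv")
    table = read_cohort_csv(path) if path.exists() else generate_cohort(spec, seed=SEED)
    return encode_dataset(table, spec, split_seed=SEED)


def main() -> None:
    data = load_data()
    OUT.mkdir(parents=True, exist_ok=True)

    qcfg = AnsatzConfig(n_qubits=11, layers=2)
    t0 = time.time()
    qres = train_vqc(qcfg, data, QTrainConfig(
        max_epochs=300, stop_patience=60, lr_patience=30, eval_every=10,
        seed=SEED,
    ))
    qacc = evaluate_accuracy(qcfg, qres.params, data, data.test_index)
    pd.DataFrame({
        "epoch": range(qres.epochs_run),
        "train_loss": qres.train_loss,
        "lr": qres.lr_trace,
    }).to_csv(OUT / "qnn_angle_L2.csv", index=False)
    print(f"QNN angle L2: {qres.epochs_run} epochs in {time.time()-t0:.0f}s, "
          f"final train loss {qres.train_loss[-1]:.4f}, "
          f"test accuracy {qacc:.4f}")

    ncfg = reference_best_nn()
    t0 = time.time()
    nres = train_nn(ncfg, data, NNTrainConfig(
        max_epochs=1500, stop_patience=300, lr_patience=100, seed=SEED,
    ))
    nacc = nn_accuracy(ncfg, nres.params, data.nn_matrix[data.test_index],
                       data.labels_01[data.test_index])
    pd.DataFrame({
        "epoch": range(nres.epochs_run),
        "train_loss": nres.train_loss,
        "test_loss": nres.monitor_loss,
        "lr": nres.lr_trace,
    }).to_csv(OUT / "nn_52x3.csv", index=False)
    print(f"NN 52-52-52: {nres.epochs_run} epochs in {time.time()-t0:.0f}s, "
          f"test accuracy {nacc:.4f}")
    print(f"histories -> {OUT}/")


if __name__ == "__main__":
    main()
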