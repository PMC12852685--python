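"""Study orchestration: grids, repeated seeds, CI aggregation, learning curves.

Every architecture is trained k times (10 in the full protocol) from
different random initializations; per-architecture test accuracies are
summarized as mean +/- a 95% Student-t confidence interval on the mean.
The sample-complexity sweep retrains the roster on random subsets of the
training partition (10%, 30%, 50%, 70%, 100%), resampling the subset for
every repeat while keeping the test partition fixed.

Budget knobs (epochs, repeats, grid caps) are first-class: the full-scale
protocol (460 quantum + 4,480 classical runs) is expressible but the
defaults here target desk scale.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classical import NNConfig, NNTrainConfig, nn_accuracy, train_nn
from .cohort import EncodedDataset, subsample_fraction
from .vqc import (
    AnsatzConfig,
    DropoutConfig,
    QTrainConfig,
    evaluate_accuracy,
    train_vqc,
)

__all__ = [
    "ModelSpec",
    "RunRecord",
    "AggregateStats",
    "enumerate_qnn_grid",
    "derive_seed",
    "run_model",
    "run_repeated",
    "aggregate",
    "accuracy",
    "select_best",
    "sample_complexity_study",
    "default_sample_complexity_roster",
    "records_to_frame",
    "aggregates_to_frame",
]

DEFAULT_FRACTIONS = (0.1, 0.3, 0.5, 0.7, 1.0)


@dataclass(frozen=True)
class ModelSpec:
    """One trainable model: a quantum (ansatz + dropout flag) or classical
    configuration plus its training schedule."""

    kind: str  # "qnn" | "nn"
    qnn: AnsatzConfig | None = None
    qnn_dropout: bool = False
    nn: NNConfig | None = None

    def __post_init__(self) -> None:
        if self.kind == "qnn" and self.qnn is None:
            raise ValueError("qnn spec needs an AnsatzConfig")
        if self.kind == "nn" and self.nn is None:
            raise ValueError("nn spec needs an NNConfig")
        if self.kind not in ("qnn", "nn"):
            raise ValueError(f"unknown model kind {self.kind!r}")

    def label(self) -> str:
        if self.kind == "nn":
            return self.nn.label()
        parts = [self.qnn.encoding, f"L{self.qnn.layers}"]
        if self.qnn.reuploading:
            parts.append("DR")
        if self.qnn_dropout:
            parts.append("dropout")
        return "qnn-" + "-".join(parts)


@dataclass
class RunRecord:
    config_id: str
    seed: int
    test_accuracy: float
    epochs: int
    error: str | None = None

    def __post_init__(self) -> None:
        if self.error is None and not 0.0 <= self.test_accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")


@dataclass
class AggregateStats:
    config_id: str
    k: int
    mean: float
    sd: float
    ci95_half_width: float


# ---------------------------------------------------------------------------
# grids

def enumerate_qnn_grid(
    n_qubits_angle: int = 11,
    n_qubits_amplitude: int = 13,
    exclude: Sequence[str] = (),
) -> list[ModelSpec]:
    """The full quantum grid: encoding x architecture x layer count.

    Rows: amplitude ansatz-repetition 1-10, amplitude + dropout 1-8, angle
    ansatz-repetition 1-10, angle + dropout 1-8, angle re-uploading 1-10,
    angle re-uploading + dropout 1-8 (54 configurations in total; dropout
    rows stop at 8 layers).  ``exclude`` drops whole rows by name, e.g.
    ``("angle-DR-dropout",)``.
    """
    rows = [
        ("amplitude", False, False, range(1, 11)),
        ("amplitude", False, True, range(1, 9)),
        ("angle", False, False, range(1, 11)),
        ("angle", False, True, range(1, 9)),
        ("angle", True, False, range(1, 11)),
        ("angle", True, True, range(1, 9)),
    ]
    out: list[ModelSpec] = []
    for encoding, reup, dropout, layer_range in rows:
        name = "-".join(
            [encoding] + (["DR"] if reup else []) + (["dropout"] if dropout else [])
        )
        if name in exclude:
            continue
        nq = n_qubits_angle if encoding == "angle" else n_qubits_amplitude
        enc = "angle" if encoding == "angle" else "amplitude_hybrid"
        for L in layer_range:
            out.append(
                ModelSpec(
                    kind="qnn",
                    qnn=AnsatzConfig(
                        n_qubits=nq, layers=L, encoding=enc, reuploading=reup
                    ),
                    qnn_dropout=dropout,
                )
            )
    return out


# ---------------------------------------------------------------------------
# runs

def derive_seed(config_id: str, repeat: int, base_seed: int) -> int:
    """Stable per-run seed from (config id, repeat index, base seed)."""
    h = zlib.crc32(f"{config_id}|{repeat}|{base_seed}".encode())
    return int(h % (2**31 - 1))


def run_model(
    spec: ModelSpec,
    data: EncodedDataset,
    seed: int,
    qtcfg: QTrainConfig | None = None,
    ntcfg: NNTrainConfig | None = None,
    train_index: np.ndarray | None = None,
) -> RunRecord:
    """Train one model once; returns its held-out accuracy."""
    cid = spec.label()
    if spec.kind == "qnn":
        tcfg = replace(qtcfg or QTrainConfig(), seed=seed)
        dropout = DropoutConfig() if spec.qnn_dropout else None
        res = train_vqc(spec.qnn, data, tcfg, dropout=dropout,
                        train_index=train_index)
        acc = evaluate_accuracy(spec.qnn, res.params, data, data.test_index)
        return RunRecord(cid, seed, acc, res.epochs_run)
    tcfg = replace(ntcfg or NNTrainConfig(), seed=seed)
    res = train_nn(spec.nn, data, tcfg, train_index=train_index)
    acc = nn_accuracy(spec.nn, res.params,
                      data.nn_matrix[data.test_index],
                      data.labels_01[data.test_index])
    return RunRecord(cid, seed, acc, res.epochs_run)


def run_repeated(
    spec: ModelSpec,
    data: EncodedDataset,
    k: int = 10,
    seed_base: int = 0,
    qtcfg: QTrainConfig | None = None,
    ntcfg: NNTrainConfig | None = None,
    train_index_fn: Callable[[int], np.ndarray] | None = None,
) -> list[RunRecord]:
    """k independent trainings with distinct derived seeds.

    Failures are recorded on the RunRecord (``error`` field), never silently
    dropped.  ``train_index_fn(repeat)`` lets the sample-complexity sweep
    hand each repeat a different training subset.
    """
    cid = spec.label()
    records: list[RunRecord] = []
    for rep in range(k):
        seed = derive_seed(cid, rep, seed_base)
        idx = train_index_fn(rep) if train_index_fn is not None else None
        try:
            records.append(
                run_model(spec, data, seed, qtcfg, ntcfg, train_index=idx)
            )
        except Exception as exc:  # noqa: BLE001 - recorded, not swallowed
            records.append(RunRecord(cid, seed, 0.0, 0, error=str(exc)))
    return records


# ---------------------------------------------------------------------------
# aggregation

def accuracy(predictions: Sequence, labels: Sequence) -> float:
    """Fraction of matching entries."""
    pred = np.asarray(predictions)
    lab = np.asarray(labels)
    if pred.shape != lab.shape or pred.size == 0:
        raise ValueError("predictions and labels must align and be non-empty")
    return float(np.mean(pred == lab))


def aggregate(records: Sequence[RunRecord]) -> AggregateStats:
    """Mean, SD and 95% Student-t CI half-width of the per-seed accuracies."""
    ok = [r for r in records if r.error is None]
    if not ok:
        raise ValueError("no successful runs to aggregate")
    acc = np.array([r.test_accuracy for r in ok])
    k = acc.size
    mean = float(acc.mean())
    sd = float(acc.std(ddof=1)) if k > 1 else 0.0
    if k > 1 and sd > 0.0:
        half = float(stats.t.ppf(0.975, k - 1) * sd / np.sqrt(k))
    else:
        half = 0.0
    return AggregateStats(ok[0].config_id, k, mean, sd, half)


def select_best(stats_list: Sequence[AggregateStats],
                n_params: dict[str, int] | None = None) -> str:
    """Best architecture: argmax mean accuracy; ties broken by tighter CI,
    then by fewer parameters when counts are supplied."""
    if not stats_list:
        raise ValueError("nothing to select from")

    def key(s: AggregateStats):
        params = (n_params or {}).get(s.config_id, 0)
        return (-s.mean, s.ci95_half_width, params)

    return min(stats_list, key=key).config_id


# ---------------------------------------------------------------------------
# sample complexity

def default_sample_complexity_roster() -> list[ModelSpec]:
    """The seven learning-curve architectures: perceptron, the reference
    3x52 network, QNNs with 1/4/9 layers, QNNs with dropout at 1/6 layers."""
    from .classical import reference_best_nn

    q = lambda L, drop=False: ModelSpec(
        kind="qnn", qnn=AnsatzConfig(n_qubits=11, layers=L), qnn_dropout=drop
    )
    return [
        ModelSpec(kind="nn", nn=NNConfig()),
        ModelSpec(kind="nn", nn=reference_best_nn()),
        q(1), q(4), q(9),
        q(1, drop=True), q(6, drop=True),
    ]


def sample_complexity_study(
    data: EncodedDataset,
    architectures: Sequence[ModelSpec] | None = None,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    repeats: int = 10,
    seed: int = 0,
    qtcfg: QTrainConfig | None = None,
    ntcfg: NNTrainConfig | None = None,
) -> tuple[pd.DataFrame, list[RunRecord]]:
    """Learning curves: accuracy vs training-set fraction.

    The test partition stays fixed; each (architecture, fraction, repeat)
    draws a fresh random training subset of the requested size.  Returns the
    aggregate table (one row per architecture x fraction) plus the full run
    ledger.
    """
    architectures = (
        list(architectures) if architectures is not None
        else default_sample_complexity_roster()
    )
    rows = []
    ledger: list[RunRecord] = []
    for spec in architectures:
        cid = spec.label()
        for f in fractions:
            def subset(rep: int, f=f, cid=cid):
                sub_seed = derive_seed(f"{cid}@{f}", rep, seed)
                return subsample_fraction(data.train_index, f, seed=sub_seed)

            records = run_repeated(
                spec, data, k=repeats, seed_base=derive_seed(cid, 0, seed) + int(f * 1000),
                qtcfg=qtcfg, ntcfg=ntcfg, train_index_fn=subset,
            )
            ledger.extend(records)
            agg = aggregate(records)
            rows.append({
                "architecture": cid,
                "fraction": f,
                "k": agg.k,
                "mean_accuracy": agg.mean,
                "sd": agg.sd,
                "ci95_half_width": agg.ci95_half_width,
            })
    return pd.DataFrame(rows), ledger


# ---------------------------------------------------------------------------
# report frames

def records_to_frame(records: Sequence[RunRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "architecture": r.config_id,
            "seed": r.seed,
            "test_accuracy": r.test_accuracy,
            "epochs": r.epochs,
            "error": r.error or "",
        }
        for r in records
    ])


def aggregates_to_frame(stats_list: Sequence[AggregateStats]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "architecture": s.config_id,
            "k": s.k,
            "mean_accuracy": s.mean,
            "sd": s.sd,
            "ci95_half_width": s.ci95_half_width,
        }
        for s in stats_list
    ])
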