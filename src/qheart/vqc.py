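"""Variational quantum classifier.

Architecture: an encoding block S(x) (angle encoding on 11 qubits, or the
13-qubit hybrid amplitude+basis encoding) followed by L ansatz layers W(θ).
One ansatz layer is

    RY on every qubit
    CZ on pairs (0,1), (2,3), ...
    RY on an interior row of qubits
    CZ on offset pairs (1,2), (3,4), ... within qubits 1..N-2

Under the default ``exclude_last_only`` convention the second RY row acts on
qubits 0..N-2, giving 2N-1 rotations per layer and (2N-1)L trainable circuit
parameters; the ``exclude_first_and_last`` variant acts on 1..N-2 (2N-2 per
layer).  With data re-uploading the encoding block is repeated before every
layer.  The classifier output is sigmoid(sum_i <Z_i> + bias), trained with
binary cross-entropy, Adam, parameter-shift gradients, optional quantum
dropout (random removal of trainable rotations), a plateau-halved learning
rate and early stopping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .quantum import (
    Circuit,
    Gate,
    _z_signs,
    all_z_expectations,
    apply_gate_inplace,
    hybrid_state_vector,
    run_circuit_array,
)

__all__ = [
    "AnsatzConfig",
    "VQCParams",
    "DropoutConfig",
    "DropoutMask",
    "QTrainConfig",
    "QTrainResult",
    "build_ansatz_layer",
    "build_model_circuit",
    "predict_proba",
    "classify",
    "bce_loss",
    "parameter_shift_gradient",
    "adjoint_gradient",
    "sample_dropout_mask",
    "init_params",
    "train_vqc",
    "gradient_statistics",
]

_EPS = 1e-12  # probability clip in the cross-entropy


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=np.float64)))


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class AnsatzConfig:
    n_qubits: int = 11
    layers: int = 1
    encoding: str = "angle"  # "angle" | "amplitude_hybrid"
    reuploading: bool = False
    second_ry_row: str = "exclude_last_only"  # | "exclude_first_and_last"

    def __post_init__(self) -> None:
        if self.encoding not in ("angle", "amplitude_hybrid"):
            raise ValueError(f"unknown encoding {self.encoding!r}")
        if self.reuploading and self.encoding != "angle":
            raise ValueError("data re-uploading applies to angle encoding only")
        if self.layers < 1:
            raise ValueError("need at least one layer")
        if self.n_qubits < 3:
            raise ValueError("the ansatz needs at least 3 qubits")
        if self.second_ry_row not in ("exclude_last_only", "exclude_first_and_last"):
            raise ValueError(f"unknown convention {self.second_ry_row!r}")

    @property
    def slots_per_layer(self) -> int:
        n = self.n_qubits
        return 2 * n - 1 if self.second_ry_row == "exclude_last_only" else 2 * n - 2

    @property
    def n_slots(self) -> int:
        return self.slots_per_layer * self.layers


@dataclass
class VQCParams:
    theta: np.ndarray
    bias: float = 0.0

    def copy(self) -> "VQCParams":
        return VQCParams(self.theta.copy(), self.bias)


@dataclass(frozen=True)
class DropoutConfig:
    p_layer: float = 0.1
    p_gate: float = 0.1

    def __post_init__(self) -> None:
        for p in (self.p_layer, self.p_gate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("dropout probabilities must lie in [0, 1]")


DropoutMask = frozenset  # of (layer, slot-within-layer) -> flat slot ids


@dataclass(frozen=True)
class QTrainConfig:
    lr0: float = 0.01
    lr_factor: float = 0.5
    lr_patience: int = 50
    stop_patience: int = 100
    n_batches: int = 10
    batch_size: int = 64
    max_epochs: int = 10_000
    init_scale: float = 0.01
    init_mean: float = 1.0
    init_sd: float = 1.0
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    eval_every: int = 1  # epochs between test-accuracy evaluations
    seed: int = 0


@dataclass
class QTrainResult:
    params: VQCParams
    train_loss: list[float]
    test_accuracy: list[float]
    lr_trace: list[float]
    epochs_run: int
    best_epoch: int


# ---------------------------------------------------------------------------
# circuit construction

def build_ansatz_layer(
    n_qubits: int, slot_offset: int = 0, convention: str = "exclude_last_only"
) -> list[Gate]:
    """One ansatz layer; trainable slots numbered from ``slot_offset``."""
    if n_qubits < 3:
        raise ValueError("the ansatz needs at least 3 qubits")
    gates: list[Gate] = []
    slot = slot_offset
    for q in range(n_qubits):
        gates.append(Gate("RY", q, slot=slot))
        slot += 1
    for q in range(0, n_qubits - 1, 2):
        gates.append(Gate("CZ", q + 1, control=q))
    if convention == "exclude_last_only":
        second_row = range(0, n_qubits - 1)
    elif convention == "exclude_first_and_last":
        second_row = range(1, n_qubits - 1)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    for q in second_row:
        gates.append(Gate("RY", q, slot=slot))
        slot += 1
    for q in range(1, n_qubits - 2, 2):
        gates.append(Gate("CZ", q + 1, control=q))
    return gates


def build_model_circuit(config: AnsatzConfig, x: Sequence[float] | None = None) -> Circuit:
    """Full model circuit for one record.

    For angle encoding ``x`` supplies the 11 feature angles (encoded once,
    or before every layer under re-uploading).  For the hybrid amplitude
    encoding the initial state is prepared separately and the circuit holds
    only the ansatz layers.
    """
    circ = Circuit(config.n_qubits)
    slot = 0

    def encode() -> None:
        if x is None:
            raise ValueError("angle encoding requires a feature vector")
        if len(x) != config.n_qubits:
            raise ValueError("feature vector length must equal qubit count")
        for q, xi in enumerate(x):
            circ.add(Gate("RY", q, angle=float(xi)))

    if config.encoding == "angle":
        if config.reuploading:
            for _ in range(config.layers):
                encode()
                for g in build_ansatz_layer(config.n_qubits, slot, config.second_ry_row):
                    circ.add(g)
                slot += config.slots_per_layer
        else:
            encode()
            for _ in range(config.layers):
                for g in build_ansatz_layer(config.n_qubits, slot, config.second_ry_row):
                    circ.add(g)
                slot += config.slots_per_layer
    else:
        for _ in range(config.layers):
            for g in build_ansatz_layer(config.n_qubits, slot, config.second_ry_row):
                circ.add(g)
            slot += config.slots_per_layer
    return circ


# ---------------------------------------------------------------------------
# forward pass

def _initial_states(config: AnsatzConfig, X: np.ndarray, B: np.ndarray | None) -> np.ndarray:
    """Batched initial amplitudes: |0..0> for angle encoding (the encoding
    gates are part of the circuit), hybrid-encoded product states otherwise."""
    n = X.shape[0]
    dim = 2**config.n_qubits
    if config.encoding == "angle":
        amps = np.zeros((n, dim))
        amps[:, 0] = 1.0
        return amps
    if B is None:
        raise ValueError("hybrid encoding needs the categorical bit block")
    return np.stack([hybrid_state_vector(X[i], B[i]) for i in range(n)])


def _batched_forward(
    config: AnsatzConfig,
    theta: np.ndarray,
    X: np.ndarray,
    B: np.ndarray | None = None,
    mask: frozenset = frozenset(),
    return_amps: bool = False,
):
    """Sum of <Z_i> (plus optionally final amplitudes) for a batch of records."""
    circ = _template_circuit(config)
    amps = _initial_states(config, X, B)
    overrides = _encoding_overrides(config, circ, X)
    amps = run_circuit_array(circ, amps, params=theta, angle_overrides=overrides,
                             masked_slots=mask)
    zsum = all_z_expectations(amps, config.n_qubits).sum(axis=-1)
    if return_amps:
        return zsum, amps
    return zsum


_TEMPLATE_CACHE: dict[AnsatzConfig, tuple[Circuit, list[int]]] = {}


def _template_circuit(config: AnsatzConfig) -> Circuit:
    """Model circuit with data-encoding gates carrying placeholder angles."""
    return _template(config)[0]


def _template(config: AnsatzConfig) -> tuple[Circuit, list[int]]:
    if config not in _TEMPLATE_CACHE:
        if config.encoding == "angle":
            circ = build_model_circuit(config, x=np.zeros(config.n_qubits))
        else:
            circ = build_model_circuit(config)
        enc_positions = [
            pos for pos, g in enumerate(circ.gates)
            if g.slot is None and g.kind == "RY"
        ]
        _TEMPLATE_CACHE[config] = (circ, enc_positions)
    return _TEMPLATE_CACHE[config]


def _encoding_overrides(
    config: AnsatzConfig, circ: Circuit, X: np.ndarray
) -> dict[int, np.ndarray] | None:
    if config.encoding != "angle":
        return None
    _, positions = _template(config)
    overrides: dict[int, np.ndarray] = {}
    for k, pos in enumerate(positions):
        q = k % config.n_qubits  # encoding rows cycle over qubits in order
        overrides[pos] = X[:, q]
    return overrides


def predict_proba(
    config: AnsatzConfig,
    params: VQCParams,
    x: Sequence[float],
    mask: frozenset = frozenset(),
    categorical_bits: Sequence[int] | None = None,
) -> float:
    """p = sigmoid(sum_i <Z_i> + bias) for a single record."""
    theta = np.asarray(params.theta, dtype=np.float64)
    if theta.shape != (config.n_slots,):
        raise ValueError(
            f"parameter vector has length {theta.size}, expected {config.n_slots}"
        )
    X = np.asarray(x, dtype=np.float64)[None, :]
    B = None
    if config.encoding == "amplitude_hybrid":
        if categorical_bits is None:
            raise ValueError("hybrid encoding needs categorical bits")
        B = np.asarray(categorical_bits)[None, :]
    zsum = _batched_forward(config, theta, X, B, mask)
    return float(sigmoid(zsum[0] + params.bias))


def classify(p: float) -> int:
    """Decision rule on the {-1, +1} label scale; p = 0.5 maps to -1."""
    return 1 if p > 0.5 else -1


def bce_loss(y01: Sequence[int], p: Sequence[float]) -> float:
    """Mean binary cross-entropy with probabilities clipped to [eps, 1-eps]."""
    y = np.asarray(y01, dtype=np.float64)
    q = np.clip(np.asarray(p, dtype=np.float64), _EPS, 1.0 - _EPS)
    if y.shape != q.shape:
        raise ValueError("label and probability vectors must align")
    return float(-np.mean(y * np.log(q) + (1.0 - y) * np.log(1.0 - q)))


# ---------------------------------------------------------------------------
# gradients

def _loss_and_chain(
    config: AnsatzConfig, params: VQCParams, X, y01, B, mask
) -> tuple[float, np.ndarray, np.ndarray]:
    zsum = _batched_forward(config, params.theta, X, B, mask)
    p = sigmoid(zsum + params.bias)
    loss = bce_loss(y01, p)
    # d(mean BCE)/d(f_i) with f = zsum + bias and p = sigmoid(f)
    chain = (p - np.asarray(y01, dtype=np.float64)) / len(y01)
    return loss, p, chain


def parameter_shift_gradient(
    config: AnsatzConfig,
    params: VQCParams,
    X: np.ndarray,
    y01: np.ndarray,
    categorical_bits: np.ndarray | None = None,
    mask: frozenset = frozenset(),
) -> tuple[np.ndarray, float, float]:
    """Batch BCE gradient via the parameter-shift rule.

    Each circuit parameter's partial of f_i = sum<Z> is evaluated as
    (f(theta_k + pi/2) - f(theta_k - pi/2)) / 2, then chained through the
    sigmoid and the cross-entropy analytically; the bias partial is
    analytic.  Returns (d_theta, d_bias, loss).
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y01 = np.asarray(y01)
    theta = np.asarray(params.theta, dtype=np.float64)
    B = categorical_bits
    loss, p, chain = _loss_and_chain(config, params, X, y01, B, mask)

    grad = np.zeros_like(theta)
    for k in range(theta.size):
        if k in mask:
            continue  # dropped rotation: gate absent, zero gradient
        shift = np.zeros_like(theta)
        shift[k] = math.pi / 2.0
        f_plus = _batched_forward(config, theta + shift, X, B, mask)
        f_minus = _batched_forward(config, theta - shift, X, B, mask)
        df = 0.5 * (f_plus - f_minus)
        grad[k] = float(chain @ df)
    d_bias = float(chain.sum())
    return grad, d_bias, loss


def adjoint_gradient(
    config: AnsatzConfig,
    params: VQCParams,
    X: np.ndarray,
    y01: np.ndarray,
    categorical_bits: np.ndarray | None = None,
    mask: frozenset = frozenset(),
) -> tuple[np.ndarray, float, float]:
    """Same gradient as :func:`parameter_shift_gradient`, one backward sweep.

    For Pauli rotations the analytic derivative equals the parameter-shift
    value exactly; this reverse sweep costs O(1) state operations per gate
    instead of two full circuit runs per parameter, and is what the training
    loop uses.  Agreement with the literal parameter-shift evaluation is
    asserted in the test suite.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y01 = np.asarray(y01)
    theta = np.asarray(params.theta, dtype=np.float64)
    B = categorical_bits
    n = config.n_qubits
    dim = 1 << n
    circ, _ = _template(config)
    overrides = _encoding_overrides(config, circ, X)

    active: list[tuple[int, Gate]] = []
    for pos, g in enumerate(circ.gates):
        if g.slot is not None and g.slot in mask:
            continue
        if g.slot is not None and g.kind != "RY":
            raise NotImplementedError("adjoint sweep covers RY-trainable circuits")
        active.append((pos, g))

    def angle_of(pos: int, g: Gate):
        if overrides is not None and pos in overrides:
            return overrides[pos]
        if g.slot is not None:
            return theta[g.slot]
        return g.angle

    # forward (the whole family is real: RY/CZ/CNOT on real initial states)
    psi = _initial_states(config, X, B)
    for pos, g in active:
        apply_gate_inplace(psi, n, g, angle_of(pos, g))

    zsum = all_z_expectations(psi, n).sum(axis=-1)
    p = sigmoid(zsum + params.bias)
    loss = bce_loss(y01, p)
    chain = (p - np.asarray(y01, dtype=np.float64)) / len(y01)

    # lambda = (sum_q Z_q) |psi>
    lam = psi * _z_signs(n).sum(axis=-1)

    grad = np.zeros_like(theta)
    nb = X.shape[0]
    for pos, g in reversed(active):
        if g.kind in ("CNOT", "CZ"):
            apply_gate_inplace(psi, n, g)  # involutions
            apply_gate_inplace(lam, n, g)
            continue
        th = angle_of(pos, g)
        if g.slot is not None:
            # df/dtheta = 2 <lam| dU/dtheta |psi_{g-1}> with dU/dtheta psi_{g-1}
            # = (-i/2) Y psi_g; for real RY circuits this reduces to the real
            # matrix [[0, -1/2], [1/2, 0]] acting on the target qubit of psi_g
            q = g.target
            hi, lo = dim >> (q + 1), 1 << q
            Pv = psi.reshape(nb, hi, 2, lo)
            Lv = lam.reshape(nb, hi, 2, lo)
            per_sample = np.einsum("bhl,bhl->b", Lv[:, :, 1, :], Pv[:, :, 0, :])
            per_sample -= np.einsum("bhl,bhl->b", Lv[:, :, 0, :], Pv[:, :, 1, :])
            grad[g.slot] += float(chain @ per_sample)
        neg = -th if np.isscalar(th) else -np.asarray(th)
        apply_gate_inplace(psi, n, g, neg)
        apply_gate_inplace(lam, n, g, neg)
    d_bias = float(chain.sum())
    return grad, d_bias, loss


# ---------------------------------------------------------------------------
# dropout / init

def sample_dropout_mask(
    dropout: DropoutConfig, config: AnsatzConfig, rng: np.random.Generator
) -> frozenset:
    """Quantum-dropout mask for one optimization step.

    Each layer is independently selected with probability p_layer; within a
    selected layer each trainable rotation is removed with probability
    p_gate, so the marginal removal probability per rotation is
    p_layer * p_gate.
    """
    dropped: set[int] = set()
    per = config.slots_per_layer
    for layer in range(config.layers):
        if rng.random() < dropout.p_layer:
            hits = rng.random(per) < dropout.p_gate
            dropped.update(layer * per + np.flatnonzero(hits))
    return frozenset(int(s) for s in dropped)


def init_params(config: AnsatzConfig, tcfg: QTrainConfig, seed: int) -> VQCParams:
    """Small-angle initialization: theta = 0.01 * Normal(mean 1, sd 1)."""
    rng = np.random.default_rng(seed)
    theta = tcfg.init_scale * rng.normal(
        tcfg.init_mean, tcfg.init_sd, size=config.n_slots
    )
    return VQCParams(theta=theta, bias=0.0)


# ---------------------------------------------------------------------------
# training

def _iter_batches(n_train: int, tcfg: QTrainConfig, rng: np.random.Generator):
    """10 batches of 64 drawn without replacement; a smaller training set is
    reshuffled and partitioned, keeping the short final batch."""
    want = tcfg.n_batches * tcfg.batch_size
    if n_train >= want:
        pick = rng.choice(n_train, size=want, replace=False)
        for b in range(tcfg.n_batches):
            yield pick[b * tcfg.batch_size : (b + 1) * tcfg.batch_size]
    else:
        perm = rng.permutation(n_train)
        for start in range(0, n_train, tcfg.batch_size):
            yield perm[start : start + tcfg.batch_size]


def _model_inputs(config: AnsatzConfig, data) -> tuple[np.ndarray, np.ndarray | None]:
    if config.encoding == "angle":
        return data.angle_matrix, None
    return data.amplitude_block, data.basis_block


def evaluate_accuracy(config: AnsatzConfig, params: VQCParams, data, idx) -> float:
    X, B = _model_inputs(config, data)
    Bs = None if B is None else B[idx]
    zsum = _batched_forward(config, params.theta, X[idx], Bs)
    p = sigmoid(zsum + params.bias)
    pred = np.where(p > 0.5, 1, -1)
    return float(np.mean(pred == data.labels_pm[idx]))


def train_vqc(
    config: AnsatzConfig,
    data,
    tcfg: QTrainConfig | None = None,
    dropout: DropoutConfig | None = None,
    train_index: np.ndarray | None = None,
    gradient: str = "adjoint",
) -> QTrainResult:
    """Train one VQC on an :class:`~qheart.cohort.EncodedDataset`.

    Adam on 10 batches of 64 per epoch; the learning rate is halved after
    ``lr_patience`` epochs without a strict decrease of the epoch-mean
    training loss, training stops after ``stop_patience`` such epochs, and
    the best-so-far parameters are returned.  The dropout mask, when
    configured, is resampled at every optimization step and disabled at
    evaluation time.  ``gradient`` selects the literal parameter-shift
    evaluation or the numerically identical adjoint sweep (default).
    """
    tcfg = tcfg or QTrainConfig()
    rng = np.random.default_rng(tcfg.seed)
    train_idx = np.asarray(
        train_index if train_index is not None else data.train_index
    )
    if train_idx.size == 0:
        raise ValueError("empty training set")
    X_all, B_all = _model_inputs(config, data)
    Xtr, ytr = X_all[train_idx], data.labels_01[train_idx]
    Btr = None if B_all is None else B_all[train_idx]

    grad_fn = adjoint_gradient if gradient == "adjoint" else parameter_shift_gradient
    params = init_params(config, tcfg, seed=int(rng.integers(2**31)))
    lr = tcfg.lr0
    m_t = np.zeros(params.theta.size + 1)
    v_t = np.zeros(params.theta.size + 1)
    step = 0

    best_loss = math.inf
    best_params = params.copy()
    best_epoch = 0
    stale = 0
    losses: list[float] = []
    test_acc: list[float] = []
    lr_trace: list[float] = []

    for epoch in range(tcfg.max_epochs):
        epoch_losses = []
        for batch in _iter_batches(train_idx.size, tcfg, rng):
            mask = (
                sample_dropout_mask(dropout, config, rng)
                if dropout is not None else frozenset()
            )
            Bb = None if Btr is None else Btr[batch]
            g_theta, g_bias, loss = grad_fn(
                config, params, Xtr[batch], ytr[batch], Bb, mask
            )
            epoch_losses.append(loss)
            g = np.concatenate([g_theta, [g_bias]])
            step += 1
            m_t = tcfg.adam_beta1 * m_t + (1 - tcfg.adam_beta1) * g
            v_t = tcfg.adam_beta2 * v_t + (1 - tcfg.adam_beta2) * g * g
            m_hat = m_t / (1 - tcfg.adam_beta1**step)
            v_hat = v_t / (1 - tcfg.adam_beta2**step)
            upd = lr * m_hat / (np.sqrt(v_hat) + tcfg.adam_eps)
            params.theta = params.theta - upd[:-1]
            params.bias = params.bias - float(upd[-1])

        mean_loss = float(np.mean(epoch_losses))
        losses.append(mean_loss)
        lr_trace.append(lr)
        if data.test_index.size and (epoch % tcfg.eval_every == 0):
            test_acc.append(evaluate_accuracy(config, params, data, data.test_index))
        # patience bookkeeping on the training cost
        if mean_loss < best_loss - 1e-8:
            best_loss = mean_loss
            best_params = params.copy()
            best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale % tcfg.lr_patience == 0:
                lr *= tcfg.lr_factor
            if stale >= tcfg.stop_patience:
                break

    return QTrainResult(
        params=best_params,
        train_loss=losses,
        test_accuracy=test_acc,
        lr_trace=lr_trace,
        epochs_run=len(losses),
        best_epoch=best_epoch,
    )


# ---------------------------------------------------------------------------
# diagnostics

def gradient_statistics(
    config: AnsatzConfig,
    data,
    n_inits: int = 10,
    seed: int = 0,
    tcfg: QTrainConfig | None = None,
) -> dict[str, float]:
    """Mean absolute initial gradient and its variance over random inits.

    A cheap barren-plateau diagnostic: small, shrinking magnitudes across
    initializations indicate a flat training landscape.  Reported, never
    asserted against.
    """
    tcfg = tcfg or QTrainConfig()
    rng = np.random.default_rng(seed)
    X, B = _model_inputs(config, data)
    idx = data.train_index[: tcfg.batch_size]
    Bb = None if B is None else B[idx]
    mags = []
    for _ in range(n_inits):
        params = init_params(config, tcfg, seed=int(rng.integers(2**31)))
        g_theta, _, _ = adjoint_gradient(
            config, params, X[idx], data.labels_01[idx], Bb
        )
        mags.append(np.abs(g_theta).mean())
    mags = np.asarray(mags)
    return {
        "mean_abs_gradient": float(mags.mean()),
        "variance": float(mags.var(ddof=0)),
        "n_inits": n_inits,
    }
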