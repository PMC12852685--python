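"""Classical baseline family: perceptron and feedforward networks.

Hand-rolled dense networks matching the study protocol exactly: Leaky-ReLU
(alpha = 0.1) hidden activations, sigmoid output, binary cross-entropy,
He-normal weight / Xavier-uniform bias initialization (He-uniform weights
and zero biases for the perceptron), inverted dropout at rate 0.2 on hidden
activations, and Adam with a plateau-halved learning rate (lr0 = 0.001,
halve after 100 stale epochs) and early stopping after 500 stale epochs
monitored on the *test* cost — as the protocol states.  That monitoring
choice leaks test information into the stopping time; a validation-split
alternative is available via ``NNTrainConfig(monitor="validation")``.

The architecture grid spans 1-5 hidden layers with widths in {4, 8, ..., 64},
non-increasing left to right, each with and without dropout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations_with_replacement
import numpy as np

__all__ = [
    "NNConfig",
    "NNParams",
    "NNTrainConfig",
    "NNTrainResult",
    "leaky_relu",
    "init_nn",
    "forward_nn",
    "nn_backward",
    "train_nn",
    "nn_accuracy",
    "enumerate_nn_grid",
    "reference_best_nn",
    "n_parameters",
]

_ALLOWED_WIDTHS = tuple(range(4, 65, 4))


@dataclass(frozen=True)
class NNConfig:
    """Hidden-layer widths (empty tuple = perceptron) and dropout flag."""

    hidden_widths: tuple[int, ...] = ()
    dropout: bool = False
    dropout_rate: float = 0.2
    leaky_alpha: float = 0.1

    def __post_init__(self) -> None:
        if len(self.hidden_widths) > 5:
            raise ValueError("at most 5 hidden layers")
        for w in self.hidden_widths:
            if w not in _ALLOWED_WIDTHS:
                raise ValueError(f"width {w} not a multiple of 4 in 4..64")
        for a, b in zip(self.hidden_widths, self.hidden_widths[1:]):
            if b > a:
                raise ValueError("widths must be non-increasing")

    @property
    def is_perceptron(self) -> bool:
        return not self.hidden_widths

    def label(self) -> str:
        if self.is_perceptron:
            base = "perceptron"
        else:
            base = "nn(" + "-".join(map(str, self.hidden_widths)) + ")"
        return base + ("+dropout" if self.dropout else "")


@dataclass
class NNParams:
    weights: list[np.ndarray]  # layer l: (fan_in, fan_out)
    biases: list[np.ndarray]

    def copy(self) -> "NNParams":
        return NNParams([w.copy() for w in self.weights],
                        [b.copy() for b in self.biases])


@dataclass(frozen=True)
class NNTrainConfig:
    lr0: float = 0.001
    lr_factor: float = 0.5
    lr_patience: int = 100
    stop_patience: int = 500
    n_batches: int = 10
    batch_size: int = 64
    max_epochs: int = 20_000
    monitor: str = "test"  # "test" (protocol) | "train" | "validation"
    validation_fraction: float = 0.15
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0


@dataclass
class NNTrainResult:
    params: NNParams
    train_loss: list[float]
    monitor_loss: list[float]
    test_accuracy: list[float]
    lr_trace: list[float]
    epochs_run: int
    best_epoch: int


def leaky_relu(z, alpha: float = 0.1):
    z = np.asarray(z, dtype=np.float64)
    return np.where(z >= 0.0, z, alpha * z)


def n_parameters(config: NNConfig, input_width: int) -> int:
    total = 0
    fan_in = input_width
    for w in (*config.hidden_widths, 1):
        total += fan_in * w + w
        fan_in = w
    return total


def init_nn(config: NNConfig, input_width: int, seed: int = 0) -> NNParams:
    """He-normal weights + Xavier-uniform biases for hidden networks;
    He-uniform weights + zero biases for the perceptron."""
    rng = np.random.default_rng(seed)
    widths = [input_width, *config.hidden_widths, 1]
    weights, biases = [], []
    for fan_in, fan_out in zip(widths, widths[1:]):
        if config.is_perceptron:
            limit = math.sqrt(6.0 / fan_in)  # He uniform
            weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            biases.append(np.zeros(fan_out))
        else:
            weights.append(rng.normal(0.0, math.sqrt(2.0 / fan_in),
                                      size=(fan_in, fan_out)))
            xav = math.sqrt(6.0 / (fan_in + fan_out))
            biases.append(rng.uniform(-xav, xav, size=fan_out))
    return NNParams(weights, biases)


def _forward_cached(config, params, X, dropout_active, rng):
    """Forward pass keeping pre-activations and dropout masks for backprop."""
    a = np.asarray(X, dtype=np.float64)
    if a.ndim == 1:
        a = a[None, :]
    acts = [a]
    pre = []
    masks = []
    n_hidden = len(params.weights) - 1
    for l in range(n_hidden):
        z = a @ params.weights[l] + params.biases[l]
        pre.append(z)
        a = leaky_relu(z, config.leaky_alpha)
        if dropout_active and config.dropout:
            keep = 1.0 - config.dropout_rate
            m = (rng.random(a.shape) < keep) / keep  # inverted scaling
            a = a * m
            masks.append(m)
        else:
            masks.append(None)
        acts.append(a)
    z_out = a @ params.weights[-1] + params.biases[-1]
    p = 1.0 / (1.0 + np.exp(-z_out[:, 0]))
    return p, acts, pre, masks


def forward_nn(
    config: NNConfig,
    params: NNParams,
    X,
    dropout_active: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Predicted probabilities in (0, 1); one per input row."""
    if dropout_active and config.dropout and rng is None:
        raise ValueError("active dropout needs a random generator")
    p, *_ = _forward_cached(config, params, X, dropout_active,
                            rng or np.random.default_rng())
    return p


def nn_backward(config, params, X, y01, dropout_active=False, rng=None):
    """Mean-BCE gradients for all weights/biases (and the loss).

    Returns (grad_weights, grad_biases, loss).  With the sigmoid output the
    output-layer delta is simply (p - y)/n.
    """
    rng = rng or np.random.default_rng()
    y = np.asarray(y01, dtype=np.float64)
    p, acts, pre, masks = _forward_cached(config, params, X, dropout_active, rng)
    n = y.size
    eps = 1e-12
    q = np.clip(p, eps, 1 - eps)
    loss = float(-np.mean(y * np.log(q) + (1 - y) * np.log(1 - q)))

    delta = ((p - y) / n)[:, None]  # (n, 1)
    gw = [np.empty_like(w) for w in params.weights]
    gb = [np.empty_like(b) for b in params.biases]
    for l in range(len(params.weights) - 1, -1, -1):
        gw[l] = acts[l].T @ delta
        gb[l] = delta.sum(axis=0)
        if l > 0:
            delta = delta @ params.weights[l].T
            if masks[l - 1] is not None:
                delta = delta * masks[l - 1]
            delta = delta * np.where(pre[l - 1] >= 0.0, 1.0, config.leaky_alpha)
    return gw, gb, loss


def nn_accuracy(config: NNConfig, params: NNParams, X, y01) -> float:
    p = forward_nn(config, params, X)
    return float(np.mean((p > 0.5).astype(int) == np.asarray(y01)))


def train_nn(
    config: NNConfig,
    data,
    tcfg: NNTrainConfig | None = None,
    train_index: np.ndarray | None = None,
) -> NNTrainResult:
    """Train one network on an :class:`~qheart.cohort.EncodedDataset`.

    Mirrors the quantum loop (Adam, 10 batches of 64, lr halving, early
    stopping, best-so-far parameters) with the classical schedule; the
    patience counters watch the configured monitor cost (test by default).
    """
    tcfg = tcfg or NNTrainConfig()
    rng = np.random.default_rng(tcfg.seed)
    train_idx = np.asarray(
        train_index if train_index is not None else data.train_index
    )
    if train_idx.size == 0:
        raise ValueError("empty training set")

    X_all, y_all = data.nn_matrix, data.labels_01
    if tcfg.monitor == "validation":
        n_val = max(1, int(round(tcfg.validation_fraction * train_idx.size)))
        perm = rng.permutation(train_idx)
        mon_idx, train_idx = perm[:n_val], np.sort(perm[n_val:])
    elif tcfg.monitor == "test":
        mon_idx = data.test_index
    else:
        mon_idx = train_idx
    Xtr, ytr = X_all[train_idx], y_all[train_idx]

    params = init_nn(config, X_all.shape[1], seed=int(rng.integers(2**31)))
    flat = lambda gw, gb: np.concatenate([g.ravel() for g in gw + gb])
    m_t = v_t = None
    lr = tcfg.lr0
    step = 0
    best_loss = math.inf
    best_params = params.copy()
    best_epoch = 0
    stale = 0
    losses, mon_losses, test_acc, lr_trace = [], [], [], []

    def monitor_cost() -> float:
        if mon_idx.size == 0:
            return losses[-1]
        p = forward_nn(config, params, X_all[mon_idx])
        eps = 1e-12
        q = np.clip(p, eps, 1 - eps)
        ym = y_all[mon_idx]
        return float(-np.mean(ym * np.log(q) + (1 - ym) * np.log(1 - q)))

    for epoch in range(tcfg.max_epochs):
        epoch_losses = []
        for batch in _iter_batches(train_idx.size, tcfg, rng):
            gw, gb, loss = nn_backward(
                config, params, Xtr[batch], ytr[batch],
                dropout_active=config.dropout, rng=rng,
            )
            epoch_losses.append(loss)
            g = flat(gw, gb)
            if m_t is None:
                m_t, v_t = np.zeros_like(g), np.zeros_like(g)
            step += 1
            m_t = tcfg.adam_beta1 * m_t + (1 - tcfg.adam_beta1) * g
            v_t = tcfg.adam_beta2 * v_t + (1 - tcfg.adam_beta2) * g * g
            m_hat = m_t / (1 - tcfg.adam_beta1**step)
            v_hat = v_t / (1 - tcfg.adam_beta2**step)
            upd = lr * m_hat / (np.sqrt(v_hat) + tcfg.adam_eps)
            off = 0
            for arr_list in (params.weights, params.biases):
                for arr in arr_list:
                    arr -= upd[off : off + arr.size].reshape(arr.shape)
                    off += arr.size

        losses.append(float(np.mean(epoch_losses)))
        mon = monitor_cost()
        mon_losses.append(mon)
        lr_trace.append(lr)
        if data.test_index.size:
            test_acc.append(
                nn_accuracy(config, params, X_all[data.test_index],
                            y_all[data.test_index])
            )
        if mon < best_loss - 1e-8:
            best_loss = mon
            best_params = params.copy()
            best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale % tcfg.lr_patience == 0:
                lr *= tcfg.lr_factor
            if stale >= tcfg.stop_patience:
                break

    return NNTrainResult(
        params=best_params,
        train_loss=losses,
        monitor_loss=mon_losses,
        test_accuracy=test_acc,
        lr_trace=lr_trace,
        epochs_run=len(losses),
        best_epoch=best_epoch,
    )


def _iter_batches(n_train: int, tcfg, rng: np.random.Generator):
    want = tcfg.n_batches * tcfg.batch_size
    if n_train >= want:
        pick = rng.choice(n_train, size=want, replace=False)
        for b in range(tcfg.n_batches):
            yield pick[b * tcfg.batch_size : (b + 1) * tcfg.batch_size]
    else:
        perm = rng.permutation(n_train)
        for start in range(0, n_train, tcfg.batch_size):
            yield perm[start : start + tcfg.batch_size]


def enumerate_nn_grid(
    max_depth: int = 5, cap: int | None = None, seed: int = 0
) -> list[NNConfig]:
    """All constraint-satisfying architectures, with and without dropout.

    Widths are multiples of 4 in [4, 64] and non-increasing left to right;
    the full enumeration is large, so ``cap`` deterministically subsamples
    (the perceptron and the reference network are always retained).
    """
    configs: list[NNConfig] = [NNConfig(), NNConfig(dropout=True)]
    for depth in range(1, max_depth + 1):
        for combo in combinations_with_replacement(reversed(_ALLOWED_WIDTHS), depth):
            configs.append(NNConfig(hidden_widths=combo))
            configs.append(NNConfig(hidden_widths=combo, dropout=True))
    if cap is not None and cap < len(configs):
        keep = {0, 1}
        ref = reference_best_nn()
        if ref in configs:
            keep.add(configs.index(ref))
        rng = np.random.default_rng(seed)
        pool = [i for i in range(len(configs)) if i not in keep]
        keep.update(rng.choice(pool, size=max(0, cap - len(keep)), replace=False))
        configs = [configs[i] for i in sorted(keep)]
    return configs


def reference_best_nn() -> NNConfig:
    """The study's best classical architecture: three hidden layers of 52."""
    return NNConfig(hidden_widths=(52, 52, 52), dropout=False)
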