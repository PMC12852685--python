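"""Synthetic heart-disease-like cohorts and the study's preprocessing.

The generator emulates the public Heart Disease (Detrano et al.) tabular
benchmark: 11 clinical predictors (5 continuous, 6 categorical) and a binary
coronary-artery-disease label at ~55% prevalence.  Continuous features come
from a Gaussian copula with the benchmark's marginal means/SDs clipped to
the observed ranges, reproducing the two robust correlation patterns of the
real data (Age vs. MaxHR strongly negative, Age vs. Oldpeak moderately
positive).  Labels come from a documented logistic model so the resulting
classification task is learnable.

Preprocessing mirrors the study protocol: z-score standardization for the
amplitude-encoded continuous block, min-max scaling onto [0, 2*pi] for angle
encoding, one-hot encoding for categoricals, label shift {0,1} -> {-1,+1}
for the quantum models, and a 70/30 train/test split.  All fit statistics
are computed on the training partition only and reused on the test side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "ContinuousMarginal",
    "CohortSpec",
    "EncodedDataset",
    "COLUMN_ORDER",
    "CONTINUOUS_FEATURES",
    "CATEGORICAL_FEATURES",
    "generate_cohort",
    "standardize",
    "scale_to_angle",
    "one_hot",
    "encode_labels",
    "split_train_test",
    "subsample_fraction",
    "encode_dataset",
    "read_cohort_csv",
    "write_cohort_csv",
]

COLUMN_ORDER = [
    "Age", "Sex", "ChestPainType", "RestingBP", "Cholesterol", "FastingBS",
    "RestingECG", "MaxHR", "ExerciseAngina", "Oldpeak", "ST_Slope",
    "HeartDisease",
]

CONTINUOUS_FEATURES = ["Age", "RestingBP", "Cholesterol", "MaxHR", "Oldpeak"]
CATEGORICAL_FEATURES = [
    "Sex", "ChestPainType", "FastingBS", "RestingECG", "ExerciseAngina",
    "ST_Slope",
]


@dataclass(frozen=True)
class ContinuousMarginal:
    mean: float
    sd: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if not self.min < self.max:
            raise ValueError("marginal requires min < max")
        if self.sd <= 0:
            raise ValueError("marginal requires sd > 0")


# benchmark summary statistics (mean, sd, min, max per continuous feature)
_DEFAULT_MARGINALS = {
    "Age": ContinuousMarginal(53.51, 9.43, 28.0, 77.0),
    "RestingBP": ContinuousMarginal(132.40, 18.5, 0.0, 200.0),
    "Cholesterol": ContinuousMarginal(198.80, 109.38, 0.0, 603.0),
    "MaxHR": ContinuousMarginal(136.80, 25.46, 60.0, 202.0),
    "Oldpeak": ContinuousMarginal(0.89, 1.07, -2.60, 6.20),
}

# level sets with frequencies matching the public benchmark's composition
_DEFAULT_LEVELS: dict[str, dict[str, float]] = {
    "Sex": {"M": 0.79, "F": 0.21},
    "ChestPainType": {"ASY": 0.54, "NAP": 0.22, "ATA": 0.19, "TA": 0.05},
    "FastingBS": {"0": 0.77, "1": 0.23},
    "RestingECG": {"Normal": 0.60, "LVH": 0.21, "ST": 0.19},
    "ExerciseAngina": {"N": 0.60, "Y": 0.40},
    "ST_Slope": {"Up": 0.43, "Flat": 0.50, "Down": 0.07},
}

# logistic label model on standardized continuous features and indicators;
# signs follow clinical direction (low MaxHR, high Oldpeak, exertional
# angina and asymptomatic chest pain all raise CAD risk)
_DEFAULT_COEFFICIENTS: dict[str, float] = {
    "Age": 0.30,
    "MaxHR": -0.80,
    "Oldpeak": 0.90,
    "RestingBP": 0.10,
    "Cholesterol": 0.05,
    "Sex=M": 0.60,
    "ChestPainType=ASY": 1.30,
    "ExerciseAngina=Y": 1.00,
    "ST_Slope=Flat": 0.90,
    "ST_Slope=Down": 0.90,
    "FastingBS=1": 0.40,
}

_DEFAULT_CORRELATIONS = {("Age", "MaxHR"): -0.40, ("Age", "Oldpeak"): 0.25}


@dataclass
class CohortSpec:
    """Full recipe for one synthetic cohort."""

    n_records: int = 918
    continuous_marginals: dict[str, ContinuousMarginal] = field(
        default_factory=lambda: dict(_DEFAULT_MARGINALS)
    )
    correlation_targets: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_CORRELATIONS)
    )
    categorical_levels: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_LEVELS.items()}
    )
    label_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COEFFICIENTS)
    )
    target_prevalence: float = 0.55
    seed: int = 0

    def validate(self) -> None:
        if self.n_records <= 0:
            raise ValueError("n_records must be positive")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target_prevalence must lie in (0, 1)")
        for name in CONTINUOUS_FEATURES:
            if name not in self.continuous_marginals:
                raise ValueError(f"missing marginal for {name}")
        for name in CATEGORICAL_FEATURES:
            levels = self.categorical_levels.get(name)
            if not levels:
                raise ValueError(f"missing levels for {name}")
            total = sum(levels.values())
            if abs(total - 1.0) > 1e-12:
                raise ValueError(
                    f"probabilities for {name} sum to {total}, expected 1"
                )
        for (a, b) in self.correlation_targets:
            for f in (a, b):
                if f not in CONTINUOUS_FEATURES:
                    raise ValueError(f"correlation target on unknown feature {f}")

    # flat plain-text (YAML) round-trip for configs
    def to_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "target_prevalence": self.target_prevalence,
            "seed": self.seed,
            "continuous_marginals": {
                k: [m.mean, m.sd, m.min, m.max]
                for k, m in self.continuous_marginals.items()
            },
            "correlation_targets": {
                f"{a}:{b}": r for (a, b), r in self.correlation_targets.items()
            },
            "categorical_levels": self.categorical_levels,
            "label_coefficients": self.label_coefficients,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSpec":
        known = {
            "n_records", "target_prevalence", "seed", "continuous_marginals",
            "correlation_targets", "categorical_levels", "label_coefficients",
        }
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown cohort config keys: {sorted(unknown)}")
        kwargs: dict = {}
        for key in ("n_records", "target_prevalence", "seed"):
            if key in d:
                kwargs[key] = d[key]
        if "continuous_marginals" in d:
            kwargs["continuous_marginals"] = {
                k: ContinuousMarginal(*v) for k, v in d["continuous_marginals"].items()
            }
        if "correlation_targets" in d:
            kwargs["correlation_targets"] = {
                tuple(k.split(":")): float(v)
                for k, v in d["correlation_targets"].items()
            }
        for key in ("categorical_levels", "label_coefficients"):
            if key in d:
                kwargs[key] = d[key]
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# generation

def generate_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Draw one cohort table.

    Continuous features: multivariate Gaussian with the spec's means/SDs and
    the target pairwise correlations, clipped to [min, max].  Categoricals:
    independent multinomials.  Label: Bernoulli from a logistic model whose
    intercept is calibrated (root-finding on the sampled linear predictor)
    so the expected prevalence equals ``target_prevalence``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_records

    # correlation matrix over the 5 continuous features
    feats = CONTINUOUS_FEATURES
    R = np.eye(len(feats))
    for (a, b), r in spec.correlation_targets.items():
        ia, ib = feats.index(a), feats.index(b)
        R[ia, ib] = R[ib, ia] = r
    # nearest-PD guard: the default targets are PD already
    w = np.linalg.eigvalsh(R)
    if w.min() <= 1e-10:
        raise ValueError("correlation targets do not form a valid matrix")
    z = rng.multivariate_normal(np.zeros(len(feats)), R, size=n, method="cholesky")

    # Age is recorded in whole years and Oldpeak to one decimal, like the
    # source data; the other three keep full precision, which also makes
    # duplicate rows measure-zero.
    data: dict[str, np.ndarray] = {}
    for j, name in enumerate(feats):
        m = spec.continuous_marginals[name]
        col = np.clip(m.mean + m.sd * z[:, j], m.min, m.max)
        if name == "Age":
            col = np.round(col).clip(m.min, m.max)
        elif name == "Oldpeak":
            col = np.round(col, 1)
        data[name] = col

    for name in CATEGORICAL_FEATURES:
        levels = list(spec.categorical_levels[name])
        probs = np.array([spec.categorical_levels[name][l] for l in levels])
        data[name] = rng.choice(levels, size=n, p=probs / probs.sum())

    table = pd.DataFrame(data)

    # linear predictor of the label model
    eta = np.zeros(n)
    for term, coef in spec.label_coefficients.items():
        if "=" in term:
            feat, level = term.split("=", 1)
            eta += coef * (table[feat].to_numpy() == level)
        else:
            m = spec.continuous_marginals[term]
            eta += coef * (table[term].to_numpy() - m.mean) / m.sd

    # intercept calibrated so mean sigmoid(eta + c) == target prevalence
    target = spec.target_prevalence
    c = brentq(lambda c0: expit(eta + c0).mean() - target, -30.0, 30.0)
    table["HeartDisease"] = (rng.random(n) < expit(eta + c)).astype(int)

    table = table[COLUMN_ORDER]
    if table.duplicated().any():
        raise RuntimeError("generated cohort contains duplicate rows")
    return table


# ---------------------------------------------------------------------------
# preprocessing primitives

def standardize(
    column: Sequence[float], fit_stats: tuple[float, float] | None = None
) -> tuple[np.ndarray, tuple[float, float]]:
    """z = (x - mu) / sigma.  Returns (values, (mu, sigma)).

    When ``fit_stats`` is given (test-time transform) those statistics are
    reused instead of refit — the leakage-free protocol.
    """
    x = np.asarray(column, dtype=np.float64)
    if fit_stats is None:
        mu = float(x.mean())
        sd = float(x.std(ddof=0))
        if sd <= 0.0:
            raise ValueError("cannot standardize a zero-variance column")
    else:
        mu, sd = fit_stats
        if sd <= 0.0:
            raise ValueError("invalid fit statistics: sd must be positive")
    return (x - mu) / sd, (mu, sd)


def scale_to_angle(
    column: Sequence[float], fit_range: tuple[float, float] | None = None
) -> tuple[np.ndarray, tuple[float, float]]:
    """Min-max map onto [0, 2*pi]; out-of-range test values are clipped."""
    x = np.asarray(column, dtype=np.float64)
    if fit_range is None:
        lo, hi = float(x.min()), float(x.max())
        if hi <= lo:
            raise ValueError("cannot angle-scale a constant column")
    else:
        lo, hi = fit_range
        if hi <= lo:
            raise ValueError("invalid fit range: max must exceed min")
    scaled = (np.clip(x, lo, hi) - lo) / (hi - lo) * (2.0 * math.pi)
    return scaled, (lo, hi)


def one_hot(
    column: Sequence, levels: Sequence[str], scheme: str = "full"
) -> np.ndarray:
    """One-hot bit matrix; ``drop_first`` omits the first (reference) level."""
    if scheme not in ("full", "drop_first"):
        raise ValueError(f"unknown one-hot scheme {scheme!r}")
    col = np.asarray(column, dtype=object).astype(str)
    levels = [str(l) for l in levels]
    unseen = set(col) - set(levels)
    if unseen:
        raise ValueError(f"unseen categorical levels: {sorted(unseen)}")
    emit = levels[1:] if scheme == "drop_first" else levels
    return np.stack([(col == l).astype(np.int64) for l in emit], axis=1)


def encode_labels(y01: Sequence[int]) -> np.ndarray:
    """{0,1} -> {-1,+1} label shift used by the quantum models."""
    y = np.asarray(y01)
    if y.size and not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")
    return (2 * y - 1).astype(np.int64)


def split_train_test(
    table: pd.DataFrame, train_fraction: float = 0.7, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint 70/30-style split; |train| = ceil(fraction * n)."""
    if not 0.0 < train_fraction <= 1.0:
        raise ValueError("train_fraction must lie in (0, 1]")
    n = len(table)
    n_train = math.ceil(train_fraction * n)
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def subsample_fraction(
    train_index: np.ndarray, fraction: float, seed: int = 0
) -> np.ndarray:
    """Draw round(f * |train|) training indices without replacement."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    train_index = np.asarray(train_index)
    if fraction == 1.0:
        return train_index.copy()
    size = int(math.floor(fraction * train_index.size + 0.5))  # round-half-up
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(train_index, size=size, replace=False))


# ---------------------------------------------------------------------------
# full encoding

@dataclass
class EncodedDataset:
    """All model-ready views of one cohort, split and leakage-free.

    angle_matrix    11 features min-max scaled to [0, 2*pi] (categoricals
                    integer-coded before scaling) — the 11-qubit angle path
    amplitude_block 5 continuous features, z-scored on train stats — the
                    3-qubit amplitude register
    basis_block     10 drop-first one-hot bits — the basis register
    nn_matrix       13-column classical design (see module docstring)
    """

    angle_matrix: np.ndarray
    amplitude_block: np.ndarray
    basis_block: np.ndarray
    nn_matrix: np.ndarray
    labels_01: np.ndarray
    labels_pm: np.ndarray
    train_index: np.ndarray
    test_index: np.ndarray

    def subset(self, which: str) -> "EncodedDataset":
        idx = self.train_index if which == "train" else self.test_index
        return EncodedDataset(
            self.angle_matrix[idx], self.amplitude_block[idx],
            self.basis_block[idx], self.nn_matrix[idx],
            self.labels_01[idx], self.labels_pm[idx],
            np.arange(idx.size), np.array([], dtype=int),
        )


def encode_dataset(
    table: pd.DataFrame,
    spec: CohortSpec | None = None,
    split_seed: int = 0,
    train_fraction: float = 0.7,
    nn_scheme: str = "compact13",
) -> EncodedDataset:
    """Build every encoding view with train-fitted statistics.

    ``nn_scheme``: ``compact13`` (default 13-column classical design) or
    ``full_onehot`` (5 standardized continuous + 16 full one-hot bits).
    """
    spec = spec or CohortSpec()
    levels = spec.categorical_levels
    train_idx, test_idx = split_train_test(table, train_fraction, split_seed)
    n = len(table)

    # ---- angle path: 11 integer-coded-then-scaled columns
    angle = np.empty((n, 11))
    order = [c for c in COLUMN_ORDER if c != "HeartDisease"]
    for j, name in enumerate(order):
        if name in CONTINUOUS_FEATURES:
            raw = table[name].to_numpy(dtype=float)
        else:
            lv = [str(l) for l in levels[name]]
            raw = np.array([lv.index(str(v)) for v in table[name]], dtype=float)
        if test_idx.size and raw[train_idx].max() == raw[train_idx].min():
            # degenerate training column (tiny cohorts): scale on full data
            scaled, rng_ = scale_to_angle(raw)
        else:
            _, rng_ = scale_to_angle(raw[train_idx])
            scaled, _ = scale_to_angle(raw, fit_range=rng_)
        angle[:, j] = scaled

    # ---- amplitude block: 5 continuous z-scored on train stats
    amp = np.empty((n, 5))
    for j, name in enumerate(CONTINUOUS_FEATURES):
        raw = table[name].to_numpy(dtype=float)
        _, stats = standardize(raw[train_idx])
        amp[:, j], _ = standardize(raw, fit_stats=stats)

    # ---- basis block: drop-first one-hot over the 6 categoricals (10 bits)
    basis_cols = [
        one_hot(table[name], list(levels[name]), scheme="drop_first")
        for name in CATEGORICAL_FEATURES
    ]
    basis = np.concatenate(basis_cols, axis=1)

    # ---- classical design matrix
    if nn_scheme == "full_onehot":
        oh = [
            one_hot(table[name], list(levels[name]), scheme="full")
            for name in CATEGORICAL_FEATURES
        ]
        nn = np.concatenate([amp] + oh, axis=1)
    elif nn_scheme == "compact13":
        parts = [amp]
        for name in ("Sex", "FastingBS", "ExerciseAngina"):
            lv = list(levels[name])
            parts.append(
                one_hot(table[name], lv, scheme="drop_first").astype(float)
            )
        parts.append(
            one_hot(table["ChestPainType"], list(levels["ChestPainType"]),
                    scheme="drop_first").astype(float)
        )
        for name in ("RestingECG", "ST_Slope"):
            lv = [str(l) for l in levels[name]]
            raw = np.array([lv.index(str(v)) for v in table[name]], dtype=float)
            if raw[train_idx].std() == 0:
                parts.append(raw[:, None])
            else:
                _, stats = standardize(raw[train_idx])
                z, _ = standardize(raw, fit_stats=stats)
                parts.append(z[:, None])
        nn = np.concatenate(parts, axis=1)
    else:
        raise ValueError(f"unknown nn_scheme {nn_scheme!r}")

    y01 = table["HeartDisease"].to_numpy(dtype=np.int64)
    return EncodedDataset(
        angle_matrix=angle,
        amplitude_block=amp,
        basis_block=basis,
        nn_matrix=nn,
        labels_01=y01,
        labels_pm=encode_labels(y01),
        train_index=train_idx,
        test_index=test_idx,
    )


# ---------------------------------------------------------------------------
# CSV I/O

def write_cohort_csv(table: pd.DataFrame, path) -> None:
    table[COLUMN_ORDER].to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    # categorical columns read as strings so integer-valued level sets
    # (FastingBS) survive the round-trip unchanged
    table = pd.read_csv(path, dtype={c: str for c in CATEGORICAL_FEATURES})
    missing = set(COLUMN_ORDER) - set(table.columns)
    if missing:
        raise ValueError(f"cohort CSV is missing columns: {sorted(missing)}")
    return table[COLUMN_ORDER]
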