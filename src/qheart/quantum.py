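"""Minimal dense statevector simulator.

States, the rotation/CNOT/CZ gate set, the three data encodings (basis,
angle, amplitude via Mottonen state preparation) and single-qubit Pauli-Z
expectations — everything the variational classifier needs, nothing more.

Basis-label convention
----------------------
A printed ket label reads ``q0 q1 ... q_{n-1}`` left to right, where qubit
``k`` is the *k-th least-significant bit* of the amplitude index.  Under this
convention the amplitude vector ``(0.4, 0.4, 0.8, 0.2)`` is the state
``0.4|00> + 0.4|10> + 0.8|01> + 0.2|11>``: vector index 1 (binary ``01``)
carries the label ``|10>``.  All label <-> index conversions in this module
use :func:`label_to_index` / :func:`index_to_label`.

Simulation is noiseless and exact (infinite-shot limit); expectation values
are computed from the amplitudes directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "QuantumState",
    "Gate",
    "Circuit",
    "label_to_index",
    "index_to_label",
    "apply_rotation",
    "apply_two_qubit",
    "basis_encode",
    "angle_encode",
    "mottonen_prepare",
    "hybrid_encode",
    "expectation_z",
    "run_circuit",
    "apply_gate_array",
    "apply_gate_inplace",
    "all_z_expectations",
]

_ROTATIONS = frozenset({"RX", "RY", "RZ"})
_TWO_QUBIT = frozenset({"CNOT", "CZ"})

NORM_ATOL = 1e-9


# ---------------------------------------------------------------------------
# labels

def label_to_index(label: str) -> int:
    """Amplitude index of the basis state printed as ``|label>``.

    Character ``j`` of the label is qubit ``j``, the ``j``-th least
    significant bit of the index, so ``label_to_index("010") == 2``.
    """
    if not label or any(c not in "01" for c in label):
        raise ValueError(f"label must be a non-empty bitstring, got {label!r}")
    return sum(int(c) << k for k, c in enumerate(label))


def index_to_label(index: int, n_qubits: int) -> str:
    """Inverse of :func:`label_to_index`."""
    return "".join(str((index >> k) & 1) for k in range(n_qubits))


# ---------------------------------------------------------------------------
# states

@dataclass
class QuantumState:
    """Pure state of ``n_qubits`` qubits as a dense complex amplitude vector."""

    n_qubits: int
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        if self.n_qubits < 1:
            raise ValueError("n_qubits must be positive")
        amps = np.asarray(self.amplitudes, dtype=np.complex128)
        if amps.shape != (2**self.n_qubits,):
            raise ValueError(
                f"amplitude vector must have length 2**{self.n_qubits}, "
                f"got shape {amps.shape}"
            )
        norm = np.linalg.norm(amps)
        if abs(norm - 1.0) > NORM_ATOL:
            raise ValueError(f"state norm {norm} deviates from 1 beyond {NORM_ATOL}")
        self.amplitudes = amps

    @classmethod
    def zero(cls, n_qubits: int) -> "QuantumState":
        amps = np.zeros(2**n_qubits, dtype=np.complex128)
        amps[0] = 1.0
        return cls(n_qubits, amps)

    def probability(self, index: int) -> float:
        return float(abs(self.amplitudes[index]) ** 2)

    def copy(self) -> "QuantumState":
        return QuantumState(self.n_qubits, self.amplitudes.copy())


# ---------------------------------------------------------------------------
# gates / circuits

@dataclass(frozen=True)
class Gate:
    """One gate: an RX/RY/RZ rotation or a CNOT/CZ entangler.

    ``slot`` marks a trainable parameter index; rotation gates with a slot
    take their angle from the parameter vector at execution time, those
    without use the fixed ``angle`` (data-encoding rotations).
    """

    kind: str
    target: int
    control: int | None = None
    angle: float | None = None
    slot: int | None = None

    def __post_init__(self) -> None:
        if self.kind in _ROTATIONS:
            if self.control is not None:
                raise ValueError(f"{self.kind} takes no control qubit")
            if self.angle is None and self.slot is None:
                raise ValueError(f"{self.kind} needs an angle or a parameter slot")
        elif self.kind in _TWO_QUBIT:
            if self.control is None:
                raise ValueError(f"{self.kind} needs a control qubit")
            if self.control == self.target:
                raise ValueError("control and target must differ")
            if self.angle is not None or self.slot is not None:
                raise ValueError(f"{self.kind} takes no angle")
        else:
            raise ValueError(f"unknown gate kind {self.kind!r}")


@dataclass
class Circuit:
    """Ordered gate list on a fixed register; ``n_slots`` trainable slots."""

    n_qubits: int
    gates: list[Gate] = field(default_factory=list)

    def __post_init__(self) -> None:
        for g in self.gates:
            self._check(g)

    def _check(self, gate: Gate) -> None:
        for q in (gate.target, gate.control):
            if q is not None and not (0 <= q < self.n_qubits):
                raise ValueError(
                    f"qubit {q} out of range for {self.n_qubits}-qubit circuit"
                )

    def add(self, gate: Gate) -> None:
        self._check(gate)
        self.gates.append(gate)

    @property
    def n_slots(self) -> int:
        slots = [g.slot for g in self.gates if g.slot is not None]
        if not slots:
            return 0
        expect = set(range(max(slots) + 1))
        if set(slots) != expect:
            raise ValueError("parameter slots are not dense 0..P-1")
        return max(slots) + 1

    def inverse(self) -> "Circuit":
        """Adjoint circuit (fixed-angle gates only)."""
        inv: list[Gate] = []
        for g in reversed(self.gates):
            if g.slot is not None:
                raise ValueError("cannot invert a circuit with unbound slots")
            if g.kind in _ROTATIONS:
                inv.append(replace(g, angle=-g.angle))
            else:
                inv.append(g)  # CNOT, CZ are involutions
        return Circuit(self.n_qubits, inv)

    # plain-text serialization: one gate per line "KIND target [control] [@angle|#slot]"
    def dumps(self) -> str:
        lines = [f"qubits {self.n_qubits}"]
        for g in self.gates:
            parts = [g.kind, str(g.target)]
            if g.control is not None:
                parts.append(str(g.control))
            if g.slot is not None:
                parts.append(f"#{g.slot}")
            elif g.angle is not None:
                parts.append(f"@{g.angle!r}")
            lines.append(" ".join(parts))
        return "\n".join(lines) + "\n"

    @classmethod
    def loads(cls, text: str) -> "Circuit":
        lines = [ln for ln in text.strip().splitlines() if ln.strip()]
        head = lines[0].split()
        if head[0] != "qubits":
            raise ValueError("circuit dump must start with 'qubits <n>'")
        circ = cls(int(head[1]))
        for ln in lines[1:]:
            parts = ln.split()
            kind, target = parts[0], int(parts[1])
            control = angle = slot = None
            rest = parts[2:]
            if rest and not rest[0].startswith(("@", "#")):
                control = int(rest[0])
                rest = rest[1:]
            if rest:
                if rest[0].startswith("@"):
                    angle = float(rest[0][1:])
                else:
                    slot = int(rest[0][1:])
            circ.add(Gate(kind, target, control=control, angle=angle, slot=slot))
        return circ


# ---------------------------------------------------------------------------
# batched array kernel
#
# States live in arrays of shape (..., 2**n); leading axes are batch axes.
# Qubit q is bit q of the trailing index, so a single-qubit gate is a
# reshape to (..., 2**(n-1-q), 2, 2**q) and a 2x2 mix of the middle axis.

def _rotation_coeffs(kind: str, theta):
    """2x2 matrix entries ((a,b),(c,d)) of Eq-style Pauli rotations.

    ``theta`` may be a scalar or an array (batched per-sample angles).
    """
    t = np.asarray(theta, dtype=np.float64)
    c, s = np.cos(t / 2.0), np.sin(t / 2.0)
    if kind == "RX":
        return c + 0j, -1j * s, -1j * s, c + 0j
    if kind == "RY":
        return c, -s, s, c  # real matrix: preserves real amplitude arrays
    if kind == "RZ":
        return np.exp(-1j * t / 2.0), 0.0 * t, 0.0 * t, np.exp(1j * t / 2.0)
    raise ValueError(f"not a rotation: {kind}")


try:  # fused in-place RY kernels; the numpy path below is the fallback
    import numba as _nb

    @_nb.njit(fastmath=True)
    def _ry_scalar_kernel(x, c, s):  # x: (m, 2, lo) float64, contiguous
        m, _, lo = x.shape
        for i in range(m):
            for j in range(lo):
                x0 = x[i, 0, j]
                x1 = x[i, 1, j]
                x[i, 0, j] = c * x0 - s * x1
                x[i, 1, j] = s * x0 + c * x1

    @_nb.njit(fastmath=True)
    def _ry_batched_kernel(x, c, s):  # x: (B, hi, 2, lo); c, s: (B,)
        nb_, hi, _, lo = x.shape
        for b in range(nb_):
            cb, sb = c[b], s[b]
            for h in range(hi):
                for j in range(lo):
                    x0 = x[b, h, 0, j]
                    x1 = x[b, h, 1, j]
                    x[b, h, 0, j] = cb * x0 - sb * x1
                    x[b, h, 1, j] = sb * x0 + cb * x1

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _apply_ry_fast(amps: np.ndarray, n_qubits: int, q: int, theta) -> bool:
    """Fused RY application; returns False when the fallback should run.

    RY has a real matrix, so a complex array can be processed through its
    float view (real and imaginary parts transform identically).
    """
    if not _HAVE_NUMBA or not amps.flags.c_contiguous:
        return False
    lo = 1 << q
    if np.iscomplexobj(amps):
        xf = amps.view(np.float64)
        lo *= 2
    else:
        if amps.dtype != np.float64:
            return False
        xf = amps
    t = np.asarray(theta, dtype=np.float64)
    c, s = np.cos(t / 2.0), np.sin(t / 2.0)
    if t.ndim == 0:
        _ry_scalar_kernel(xf.reshape(-1, 2, lo), float(c), float(s))
        return True
    if t.ndim == 1 and amps.ndim == 2 and t.shape[0] == amps.shape[0]:
        hi = xf.shape[-1] // (2 * lo)
        _ry_batched_kernel(
            xf.reshape(t.shape[0], hi, 2, lo),
            np.ascontiguousarray(c), np.ascontiguousarray(s),
        )
        return True
    return False


def _two_qubit_view(amps: np.ndarray, n_qubits: int, qa: int, qb: int):
    """Reshape so axes for qubits ``qa`` > ``qb`` are exposed:
    (..., hi, 2[qa], mid, 2[qb], lo)."""
    batch = amps.shape[:-1]
    hi = 1 << (n_qubits - 1 - qa)
    mid = 1 << (qa - qb - 1)
    lo = 1 << qb
    return amps.reshape(batch + (hi, 2, mid, 2, lo))


def apply_gate_inplace(amps: np.ndarray, n_qubits: int, gate: Gate, theta=None) -> np.ndarray:
    """In-place gate application on a (batched) amplitude array.

    The array may be real: RY, CNOT and CZ have real matrices and preserve a
    real dtype (the whole classifier circuit family is real); RX/RZ require a
    complex array.  ``theta`` overrides the gate's angle and may be an array
    broadcasting over leading batch axes.
    """
    dim = 1 << n_qubits
    if amps.shape[-1] != dim:
        raise ValueError("amplitude array does not match qubit count")
    q = gate.target
    if gate.kind in _ROTATIONS:
        if theta is None:
            theta = gate.angle
        if theta is None:
            raise ValueError("unbound parameter slot")
        if gate.kind != "RY" and not np.iscomplexobj(amps):
            raise TypeError(f"{gate.kind} on a real amplitude array")
        if gate.kind == "RY" and _apply_ry_fast(amps, n_qubits, q, theta):
            return amps
        a, b, c, d = _rotation_coeffs(gate.kind, theta)
        x = amps.reshape(amps.shape[:-1] + (dim >> (q + 1), 2, 1 << q))
        if np.ndim(theta):  # per-sample angles
            sh = np.shape(theta) + (1, 1)
            a, b, c, d = (np.reshape(v, sh) for v in (a, b, c, d))
        x0 = x[..., 0, :]
        x1 = x[..., 1, :]
        t = a * x0 + b * x1
        x1 *= d
        x1 += c * x0
        x0[...] = t
        return amps
    ctrl = gate.control
    qa, qb = (ctrl, q) if ctrl > q else (q, ctrl)
    v = _two_qubit_view(amps, n_qubits, qa, qb)
    # axis positions: -4 is qubit qa, -2 is qubit qb
    if gate.kind == "CZ":
        v[..., 1, :, 1, :] *= -1.0
        return amps
    if gate.kind == "CNOT":
        # flip the target bit where the control bit is 1
        if ctrl > q:  # control on axis -4, target on axis -2
            blk = v[..., 1, :, :, :]
            blk[...] = blk[..., ::-1, :]
        else:  # control on axis -2, target on axis -4
            blk = v[..., :, :, 1, :]
            blk[...] = blk[..., ::-1, :, :]
        return amps
    raise ValueError(f"unknown gate kind {gate.kind!r}")


def apply_gate_array(
    amps: np.ndarray, n_qubits: int, gate: Gate, theta=None
) -> np.ndarray:
    """Like :func:`apply_gate_inplace` but returns a fresh array."""
    out = amps.copy()
    if gate.kind in ("RX", "RZ") and not np.iscomplexobj(out):
        out = out.astype(np.complex128)
    return apply_gate_inplace(out, n_qubits, gate, theta)


def run_circuit_array(
    circuit: Circuit,
    amps: np.ndarray,
    params: np.ndarray | None = None,
    angle_overrides: dict[int, np.ndarray] | None = None,
    masked_slots: frozenset[int] | set[int] = frozenset(),
) -> np.ndarray:
    """Run a circuit on a raw (batched) amplitude array.

    ``angle_overrides`` maps gate positions (index into ``circuit.gates``)
    to per-sample angle arrays — used for batched data encoding.  Gates whose
    slot is in ``masked_slots`` are skipped (quantum dropout).  The input
    array is not modified.
    """
    if any(g.kind in ("RX", "RZ") for g in circuit.gates):
        amps = amps.astype(np.complex128)
    else:
        amps = amps.copy()
    for pos, g in enumerate(circuit.gates):
        if g.slot is not None and g.slot in masked_slots:
            continue
        theta = None
        if angle_overrides is not None and pos in angle_overrides:
            theta = angle_overrides[pos]
        elif g.slot is not None:
            if params is None:
                raise ValueError("circuit has parameter slots but no params given")
            theta = params[g.slot]
        apply_gate_inplace(amps, circuit.n_qubits, g, theta)
    return amps


_SIGNS_CACHE: dict[int, np.ndarray] = {}


def _z_signs(n_qubits: int) -> np.ndarray:
    if n_qubits not in _SIGNS_CACHE:
        idx = np.arange(2**n_qubits)
        _SIGNS_CACHE[n_qubits] = np.stack(
            [1.0 - 2.0 * ((idx >> q) & 1) for q in range(n_qubits)], axis=-1
        )
    return _SIGNS_CACHE[n_qubits]


def all_z_expectations(amps: np.ndarray, n_qubits: int) -> np.ndarray:
    """<Z_q> for every qubit; returns shape ``batch + (n_qubits,)``."""
    if np.iscomplexobj(amps):
        probs = amps.real**2 + amps.imag**2
    else:
        probs = amps**2
    return probs @ _z_signs(n_qubits)


# ---------------------------------------------------------------------------
# public single-state operations

def apply_rotation(state: QuantumState, axis: str, qubit: int, theta: float) -> QuantumState:
    """Apply the Pauli rotation R_axis(theta) to one qubit."""
    axis = axis.upper()
    if axis not in ("X", "Y", "Z"):
        raise ValueError(f"axis must be X, Y or Z, got {axis!r}")
    if not (0 <= qubit < state.n_qubits):
        raise ValueError(f"qubit {qubit} out of range")
    gate = Gate("R" + axis, qubit, angle=theta)
    return QuantumState(
        state.n_qubits, apply_gate_array(state.amplitudes, state.n_qubits, gate)
    )


def apply_two_qubit(state: QuantumState, kind: str, control: int, target: int) -> QuantumState:
    """Apply CNOT or CZ on (control, target)."""
    gate = Gate(kind.upper(), target, control=control)
    if not (0 <= control < state.n_qubits) or not (0 <= target < state.n_qubits):
        raise ValueError("qubit index out of range")
    return QuantumState(
        state.n_qubits, apply_gate_array(state.amplitudes, state.n_qubits, gate)
    )


def basis_encode(bits: Sequence[int] | str) -> QuantumState:
    """Load a bitstring onto qubits: ``"010"`` becomes the state |010>."""
    if isinstance(bits, str):
        label = bits
    else:
        label = "".join(str(int(b)) for b in bits)
    if not label:
        raise ValueError("cannot basis-encode an empty bit vector")
    n = len(label)
    amps = np.zeros(2**n, dtype=np.complex128)
    amps[label_to_index(label)] = 1.0
    return QuantumState(n, amps)


def angle_encode(x: Sequence[float]) -> Circuit:
    """Angle encoding: one RY(x_i) per qubit, one qubit per feature."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("angle_encode expects a non-empty 1-D vector")
    if np.any(x < -1e-12) or np.any(x > 2 * math.pi + 1e-12):
        raise ValueError("angle-encoded features must lie in [0, 2*pi]")
    circ = Circuit(x.size)
    for q, xi in enumerate(x):
        circ.add(Gate("RY", q, angle=float(xi)))
    return circ


def expectation_z(state: QuantumState, qubit: int) -> float:
    """<Z> of one qubit: P(qubit=0) - P(qubit=1)."""
    if not (0 <= qubit < state.n_qubits):
        raise ValueError(f"qubit {qubit} out of range")
    return float(all_z_expectations(state.amplitudes, state.n_qubits)[qubit])


def run_circuit(
    circuit: Circuit,
    initial: QuantumState | None = None,
    params: np.ndarray | None = None,
) -> QuantumState:
    """Execute a circuit from |0...0> (or a given initial state), exactly."""
    if initial is None:
        initial = QuantumState.zero(circuit.n_qubits)
    elif initial.n_qubits != circuit.n_qubits:
        raise ValueError("initial state size does not match circuit")
    amps = run_circuit_array(circuit, initial.amplitudes.copy(), params=params)
    return QuantumState(circuit.n_qubits, amps)


# ---------------------------------------------------------------------------
# Mottonen state preparation (real amplitudes)

def _gray(i: int) -> int:
    return i ^ (i >> 1)


def _uniformly_controlled_ry(
    circ: Circuit, target: int, controls: list[int], alphas: np.ndarray
) -> None:
    """Append a uniformly controlled RY: rotate ``target`` by ``alphas[j]``
    when the control register (little-endian over ``controls``) reads ``j``.

    Decomposed into 2**k RY gates interleaved with CNOTs via the Gray-code
    construction; with no controls it is a single RY.
    """
    k = len(controls)
    if k == 0:
        circ.add(Gate("RY", target, angle=float(alphas[0])))
        return
    m = 1 << k
    # theta_i = 2^-k * sum_j (-1)^(popcount(j & gray(i))) alpha_j
    thetas = np.empty(m)
    for i in range(m):
        g = _gray(i)
        signs = np.array([(-1) ** bin(j & g).count("1") for j in range(m)])
        thetas[i] = float(signs @ alphas) / m
    for i in range(m):
        circ.add(Gate("RY", target, angle=float(thetas[i])))
        # control line flips where gray(i) and gray(i+1 mod m) differ
        diff = _gray(i) ^ _gray((i + 1) % m)
        ctrl = controls[diff.bit_length() - 1]
        circ.add(Gate("CNOT", target, control=ctrl))


def mottonen_prepare(v: Sequence[float]) -> Circuit:
    """Mottonen state preparation of a real unit vector of length 2**k.

    The returned circuit maps |0...0> to the state whose amplitude vector
    equals ``v`` (entrywise, under the module's index convention).  Only the
    RY cascade is built — sufficient for real (possibly signed) amplitudes;
    the RZ phase stage needed for complex targets is intentionally absent.
    """
    v = np.asarray(v, dtype=np.float64)
    if v.ndim != 1 or v.size < 2 or (v.size & (v.size - 1)) != 0:
        raise ValueError("input must be a 1-D real vector of length 2**k >= 2")
    if abs(np.linalg.norm(v) - 1.0) > NORM_ATOL:
        raise ValueError("input vector must be L2-normalized")
    n = int(math.log2(v.size))
    circ = Circuit(n)
    # level s rotates qubit s, controlled on qubits s+1..n-1; blocks of the
    # target vector of size 2**s are split by bit s.
    for s in range(n - 1, -1, -1):
        n_ctrl = n - 1 - s
        alphas = np.empty(1 << n_ctrl)
        for j in range(1 << n_ctrl):
            base = j << (s + 1)
            lo = v[base : base + (1 << s)]
            hi = v[base + (1 << s) : base + (1 << (s + 1))]
            if s == 0:
                # leaf level: signed pair (a, b) -> angle 2*atan2(b, a)
                alphas[j] = 2.0 * math.atan2(hi[0], lo[0])
            else:
                alphas[j] = 2.0 * math.atan2(
                    float(np.linalg.norm(hi)), float(np.linalg.norm(lo))
                )
        controls = list(range(s + 1, n))
        _uniformly_controlled_ry(circ, s, controls, alphas)
    return circ


def hybrid_encode(
    continuous5: Sequence[float], categorical_bits: Sequence[int] | str
) -> QuantumState:
    """13-qubit hybrid encoding: amplitude register (x) basis register.

    The five standardized continuous values are padded with three zeros,
    L2-normalized and amplitude-encoded on 3 qubits (qubits 0-2); the ten
    categorical bits are basis-encoded on qubits 3-12.  The result is the
    product state of the two registers.
    """
    cont = np.asarray(continuous5, dtype=np.float64)
    if cont.shape != (5,):
        raise ValueError("continuous block must have exactly 5 values")
    if isinstance(categorical_bits, str):
        bits = categorical_bits
    else:
        bits = "".join(str(int(b)) for b in categorical_bits)
    if len(bits) != 10 or any(c not in "01" for c in bits):
        raise ValueError("categorical block must be 10 bits")
    padded = np.zeros(8)
    padded[:5] = cont
    norm = np.linalg.norm(padded)
    if norm < 1e-12:
        padded[0] = 1.0  # all-zero record: fall back to |000>
    else:
        padded = padded / norm
    amp_reg = run_circuit(mottonen_prepare(padded)).amplitudes
    basis_reg = basis_encode(bits).amplitudes
    # qubits 0-2 are the low bits of the index: full = kron(high, low)
    full = np.kron(basis_reg, amp_reg)
    return QuantumState(13, full)


def hybrid_state_vector(continuous5: np.ndarray, categorical_bits: np.ndarray) -> np.ndarray:
    """Fast direct construction of the hybrid-encoded amplitudes (no circuit).

    Used by the training loop; agreement with :func:`hybrid_encode` (which
    runs the actual Mottonen circuit) is asserted in the test suite.
    """
    padded = np.zeros(8)
    padded[:5] = continuous5
    norm = np.linalg.norm(padded)
    if norm < 1e-12:
        padded[0] = 1.0
    else:
        padded = padded / norm
    amps = np.zeros(2**13)
    offset = label_to_index("".join(str(int(b)) for b in categorical_bits)) << 3
    amps[offset : offset + 8] = padded
    return amps
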