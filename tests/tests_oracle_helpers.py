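"""Shared independent oracles for simulator tests: explicit dense-matrix
circuit construction via Kronecker products, random circuits and states."""

import math

import numpy as np

from qheart.quantum import Circuit, Gate


def rot_matrix(axis: str, t: float) -> np.ndarray:
    c, s = math.cos(t / 2), math.sin(t / 2)
    if axis == "X":
        return np.array([[c, -1j * s], [-1j * s, c]])
    if axis == "Y":
        return np.array([[c, -s], [s, c]], dtype=complex)
    return np.diag([np.exp(-1j * t / 2), np.exp(1j * t / 2)])


CNOT_MAT = np.array(
    [[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 0, 1], [0, 0, 1, 0]], dtype=complex
)
CZ_MAT = np.diag([1, 1, 1, -1]).astype(complex)


def dense_unitary(circuit: Circuit) -> np.ndarray:
    """Full 2^n x 2^n matrix of a circuit (index bit k = qubit k)."""
    n = circuit.n_qubits
    dim = 2**n
    U = np.eye(dim, dtype=complex)
    for g in circuit.gates:
        if g.kind in ("RX", "RY", "RZ"):
            factors = [np.eye(2, dtype=complex)] * n
            factors[g.target] = rot_matrix(g.kind[1], g.angle)
            M = factors[n - 1]
            for k in range(n - 2, -1, -1):
                M = np.kron(M, factors[k])
        else:
            base = CNOT_MAT if g.kind == "CNOT" else CZ_MAT
            M = np.zeros((dim, dim), dtype=complex)
            for i in range(dim):
                for j in range(dim):
                    ci, ti = (i >> g.control) & 1, (i >> g.target) & 1
                    cj, tj = (j >> g.control) & 1, (j >> g.target) & 1
                    rest_i = i & ~((1 << g.control) | (1 << g.target))
                    rest_j = j & ~((1 << g.control) | (1 << g.target))
                    if rest_i == rest_j:
                        M[i, j] = base[2 * ci + ti, 2 * cj + tj]
        U = M @ U
    return U


def random_state(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=2**n) + 1j * rng.normal(size=2**n)
    return v / np.linalg.norm(v)


def random_circuit(rng: np.random.Generator, n: int, n_gates: int) -> Circuit:
    circ = Circuit(n)
    for _ in range(n_gates):
        kind = rng.choice(["RX", "RY", "RZ", "CNOT", "CZ"])
        if kind in ("CNOT", "CZ"):
            c, t = rng.choice(n, size=2, replace=False)
            circ.add(Gate(kind, int(t), control=int(c)))
        else:
            circ.add(
                Gate(kind, int(rng.integers(n)),
                     angle=float(rng.uniform(0, 2 * math.pi)))
            )
    return circ
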