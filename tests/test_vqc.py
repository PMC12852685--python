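"""Variational classifier: ansatz bookkeeping, forward pass, gradients,
dropout, initialization and the training loop."""

import math

import numpy as np
import pytest

from qheart.quantum import Circuit, Gate, expectation_z, run_circuit
from qheart.vqc import (
    AnsatzConfig,
    DropoutConfig,
    QTrainConfig,
    VQCParams,
    adjoint_gradient,
    bce_loss,
    build_ansatz_layer,
    build_model_circuit,
    classify,
    evaluate_accuracy,
    gradient_statistics,
    init_params,
    parameter_shift_gradient,
    predict_proba,
    sample_dropout_mask,
    train_vqc,
)
from qheart.vqc import _batched_forward, sigmoid


class TestAnsatzLayer:
    def test_formula_count_default_convention(self):
        # (2N-1) rotations per layer at N=11
        gates = build_ansatz_layer(11)
        assert sum(g.slot is not None for g in gates) == 21

    def test_prose_convention_count(self):
        gates = build_ansatz_layer(11, convention="exclude_first_and_last")
        assert sum(g.slot is not None for g in gates) == 20

    @pytest.mark.parametrize("n", range(3, 14))
    @pytest.mark.parametrize("layers", [1, 4, 10])
    def test_slot_counts_both_conventions(self, n, layers):
        default = AnsatzConfig(n_qubits=n, layers=layers)
        prose = AnsatzConfig(n_qubits=n, layers=layers,
                             second_ry_row="exclude_first_and_last")
        assert default.n_slots == (2 * n - 1) * layers
        assert prose.n_slots == (2 * n - 2) * layers

    def test_first_cz_row_pairs(self):
        gates = build_ansatz_layer(4)
        cz = [(g.control, g.target) for g in gates if g.kind == "CZ"]
        assert cz[:2] == [(0, 1), (2, 3)]
        # second row: offset pairs within the interior
        assert cz[2:] == [(1, 2)]

    def test_too_few_qubits(self):
        with pytest.raises(ValueError):
            build_ansatz_layer(2)


class TestModelCircuit:
    def test_reuploading_repeats_encoding(self):
        x = np.linspace(0.1, 2.0, 4)
        cfg = AnsatzConfig(n_qubits=4, layers=2, reuploading=True)
        circ = build_model_circuit(cfg, x)
        enc = [g for g in circ.gates if g.slot is None and g.kind == "RY"]
        assert len(enc) == 8  # 4 features x 2 layers

    def test_single_layer_reuploading_equivalence(self):
        x = np.linspace(0.1, 2.0, 4)
        a = build_model_circuit(AnsatzConfig(n_qubits=4, layers=1), x)
        b = build_model_circuit(
            AnsatzConfig(n_qubits=4, layers=1, reuploading=True), x
        )
        assert a.gates == b.gates

    def test_slot_bookkeeping(self):
        cfg = AnsatzConfig(n_qubits=5, layers=3)
        circ = build_model_circuit(cfg, np.zeros(5))
        assert circ.n_slots == cfg.n_slots == cfg.slots_per_layer * 3

    def test_reuploading_requires_angle(self):
        with pytest.raises(ValueError):
            AnsatzConfig(n_qubits=13, encoding="amplitude_hybrid", reuploading=True)


class TestForwardPass:
    def test_zero_params_zero_input_closed_form(self):
        # theta = 0, x = 0: every qubit stays |0>, sum<Z> = N
        cfg = AnsatzConfig(n_qubits=4, layers=1)
        params = VQCParams(np.zeros(cfg.n_slots), bias=0.0)
        p = predict_proba(cfg, params, np.zeros(4))
        assert p == pytest.approx(sigmoid(4.0))

    def test_balanced_state_gives_half(self):
        # x = pi/2 on every qubit with theta = 0: each <Z> = 0
        cfg = AnsatzConfig(n_qubits=3, layers=1)
        params = VQCParams(np.zeros(cfg.n_slots), bias=0.0)
        p = predict_proba(cfg, params, np.full(3, math.pi / 2))
        assert p == pytest.approx(0.5)

    def test_matches_explicit_circuit_execution(self, rng):
        # forward pass equals running the built circuit gate by gate
        cfg = AnsatzConfig(n_qubits=3, layers=2)
        params = VQCParams(rng.normal(size=cfg.n_slots), bias=0.2)
        x = rng.uniform(0, 2 * math.pi, size=3)
        circ = build_model_circuit(cfg, x)
        st = run_circuit(circ, params=params.theta)
        zsum = sum(expectation_z(st, q) for q in range(3))
        assert predict_proba(cfg, params, x) == pytest.approx(
            float(sigmoid(zsum + 0.2)), abs=1e-10
        )

    def test_param_length_mismatch(self):
        cfg = AnsatzConfig(n_qubits=4, layers=2)
        with pytest.raises(ValueError):
            predict_proba(cfg, VQCParams(np.zeros(3)), np.zeros(4))


class TestClassify:
    @pytest.mark.parametrize("p,label", [(0.9, 1), (0.1, -1), (0.5, -1)])
    def test_rule(self, p, label):
        assert classify(p) == label


class TestBceLoss:
    def test_perfect_predictions(self):
        assert bce_loss([1, 0], [1.0, 0.0]) == pytest.approx(0.0, abs=1e-10)

    def test_half_probability(self):
        assert bce_loss([1], [0.5]) == pytest.approx(math.log(2))

    def test_clipping_keeps_finite(self):
        val = bce_loss([1], [0.0])
        assert np.isfinite(val)
        assert val == pytest.approx(-math.log(1e-12))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            bce_loss([1, 0], [0.5])


class TestGradients:
    def test_single_qubit_closed_form(self):
        # f(theta) = <Z> after RY(theta): parameter-shift gives -sin(theta)
        circ = Circuit(1, [Gate("RY", 0, slot=0)])
        theta = 0.83

        def f(t):
            st = run_circuit(circ, params=np.array([t]))
            return expectation_z(st, 0)

        shift = 0.5 * (f(theta + math.pi / 2) - f(theta - math.pi / 2))
        assert shift == pytest.approx(-math.sin(theta), abs=1e-12)
        assert f(theta) == pytest.approx(math.cos(theta), abs=1e-12)
        # stationary point at theta = 0
        assert 0.5 * (f(math.pi / 2) - f(-math.pi / 2)) == pytest.approx(0.0, abs=1e-12)

    def test_parameter_shift_vs_finite_differences(self, rng):
        cfg = AnsatzConfig(n_qubits=4, layers=2)
        params = VQCParams(rng.normal(size=cfg.n_slots), bias=0.1)
        X = rng.uniform(0, 2 * math.pi, size=(6, 4))
        y = rng.integers(0, 2, size=6)
        grad, gbias, _ = parameter_shift_gradient(cfg, params, X, y)

        h = 1e-5

        def loss_at(theta, bias):
            z = _batched_forward(cfg, theta, X, None)
            return bce_loss(y, sigmoid(z + bias))

        for k in range(cfg.n_slots):
            e = np.zeros(cfg.n_slots)
            e[k] = h
            fd = (loss_at(params.theta + e, 0.1) - loss_at(params.theta - e, 0.1)) / (2 * h)
            assert grad[k] == pytest.approx(fd, abs=1e-5)
        fd_b = (loss_at(params.theta, 0.1 + h) - loss_at(params.theta, 0.1 - h)) / (2 * h)
        assert gbias == pytest.approx(fd_b, abs=1e-5)

    @pytest.mark.parametrize("cfg", [
        AnsatzConfig(n_qubits=4, layers=2),
        AnsatzConfig(n_qubits=4, layers=3, reuploading=True),
        AnsatzConfig(n_qubits=5, layers=1,
                     second_ry_row="exclude_first_and_last"),
    ], ids=["plain", "reuploading", "prose-row"])
    def test_adjoint_equals_parameter_shift(self, cfg, rng):
        # the fast adjoint sweep must reproduce the parameter-shift values
        params = VQCParams(rng.normal(size=cfg.n_slots), bias=-0.3)
        X = rng.uniform(0, 2 * math.pi, size=(5, cfg.n_qubits))
        y = rng.integers(0, 2, size=5)
        g1, b1, l1 = parameter_shift_gradient(cfg, params, X, y)
        g2, b2, l2 = adjoint_gradient(cfg, params, X, y)
        np.testing.assert_allclose(g1, g2, atol=1e-10)
        assert b1 == pytest.approx(b2, abs=1e-12)
        assert l1 == pytest.approx(l2, abs=1e-12)

    def test_adjoint_equals_parameter_shift_hybrid(self, rng):
        cfg = AnsatzConfig(n_qubits=13, layers=1, encoding="amplitude_hybrid")
        params = VQCParams(0.1 * rng.normal(size=cfg.n_slots))
        X = rng.normal(size=(3, 5))
        B = rng.integers(0, 2, size=(3, 10))
        y = rng.integers(0, 2, size=3)
        g1, b1, _ = parameter_shift_gradient(cfg, params, X, y, B)
        g2, b2, _ = adjoint_gradient(cfg, params, X, y, B)
        np.testing.assert_allclose(g1, g2, atol=1e-10)

    def test_masked_slots_have_zero_gradient(self, rng):
        cfg = AnsatzConfig(n_qubits=4, layers=2)
        params = VQCParams(rng.normal(size=cfg.n_slots))
        X = rng.uniform(0, 2 * math.pi, size=(4, 4))
        y = rng.integers(0, 2, size=4)
        mask = frozenset({1, 6})
        g, _, _ = parameter_shift_gradient(cfg, params, X, y, mask=mask)
        assert g[1] == 0.0 and g[6] == 0.0
        g2, _, _ = adjoint_gradient(cfg, params, X, y, mask=mask)
        np.testing.assert_allclose(g, g2, atol=1e-10)


class TestDropout:
    def test_zero_gate_probability_empty(self, rng):
        cfg = AnsatzConfig(n_qubits=4, layers=3)
        mask = sample_dropout_mask(DropoutConfig(p_layer=1.0, p_gate=0.0), cfg, rng)
        assert mask == frozenset()

    def test_certain_dropout_removes_all(self, rng):
        cfg = AnsatzConfig(n_qubits=4, layers=2)
        mask = sample_dropout_mask(DropoutConfig(p_layer=1.0, p_gate=1.0), cfg, rng)
        assert mask == frozenset(range(cfg.n_slots))

    @pytest.mark.parametrize("pl,pg", [(0.1, 0.1), (0.5, 0.2), (0.3, 0.6)])
    def test_marginal_rate(self, pl, pg):
        # empirical per-slot drop frequency ~ p_layer * p_gate (3 SE band)
        cfg = AnsatzConfig(n_qubits=4, layers=4)
        rng = np.random.default_rng(99)
        dcfg = DropoutConfig(p_layer=pl, p_gate=pg)
        draws = 20_000
        hits = np.zeros(cfg.n_slots)
        for _ in range(draws):
            for s in sample_dropout_mask(dcfg, cfg, rng):
                hits[s] += 1
        p = pl * pg
        se = math.sqrt(p * (1 - p) / draws)
        assert abs(hits.mean() / draws - p) < 3 * se


class TestInit:
    def test_length_matches_formula(self):
        cfg = AnsatzConfig(n_qubits=11, layers=3)
        params = init_params(cfg, QTrainConfig(), seed=0)
        assert params.theta.size == (2 * 11 - 1) * 3
        assert params.bias == 0.0

    def test_moments_of_stated_distribution(self):
        # theta = 0.01 * N(1, 1): mean 0.01, sd 0.01
        cfg = AnsatzConfig(n_qubits=13, layers=10)
        draws = np.concatenate([
            init_params(cfg, QTrainConfig(), seed=s).theta for s in range(400)
        ])
        assert draws.mean() == pytest.approx(0.01, abs=3 * 0.01 / math.sqrt(draws.size))
        assert draws.std() == pytest.approx(0.01, rel=0.02)

    def test_seed_determinism(self):
        cfg = AnsatzConfig(n_qubits=5, layers=2)
        a = init_params(cfg, QTrainConfig(), seed=7)
        b = init_params(cfg, QTrainConfig(), seed=7)
        np.testing.assert_array_equal(a.theta, b.theta)


def _toy_separable_dataset(n=80, seed=0):
    """Two clearly separated feature clusters on 3 qubits."""
    from qheart.cohort import EncodedDataset, encode_labels

    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    x = np.where(y[:, None] == 1, 2.6, 0.6) + rng.normal(0, 0.15, size=(n, 3))
    x = np.clip(x, 0, 2 * math.pi)
    tr = np.arange(0, int(0.75 * n))
    te = np.arange(int(0.75 * n), n)
    return EncodedDataset(
        angle_matrix=x, amplitude_block=x[:, :3], basis_block=np.zeros((n, 1)),
        nn_matrix=x, labels_01=y, labels_pm=encode_labels(y),
        train_index=tr, test_index=te,
    )


class TestTraining:
    def test_learns_separable_task(self):
        data = _toy_separable_dataset()
        cfg = AnsatzConfig(n_qubits=3, layers=2)
        wins = 0
        for seed in range(5):
            tcfg = QTrainConfig(max_epochs=120, stop_patience=40, lr_patience=20,
                                seed=seed)
            res = train_vqc(cfg, data, tcfg)
            acc = evaluate_accuracy(cfg, res.params, data, data.train_index)
            wins += acc >= 0.95
        assert wins >= 4

    def test_fixed_seed_reproducible(self, small_encoded):
        cfg = AnsatzConfig(n_qubits=11, layers=1)
        tcfg = QTrainConfig(max_epochs=4, seed=21)
        a = train_vqc(cfg, small_encoded, tcfg)
        b = train_vqc(cfg, small_encoded, tcfg)
        assert a.train_loss == b.train_loss
        np.testing.assert_array_equal(a.params.theta, b.params.theta)

    def test_best_so_far_non_increasing(self, small_encoded):
        cfg = AnsatzConfig(n_qubits=11, layers=1)
        res = train_vqc(cfg, small_encoded, QTrainConfig(max_epochs=15, seed=2))
        best = np.minimum.accumulate(res.train_loss)
        assert all(b2 <= b1 + 1e-12 for b1, b2 in zip(best, best[1:]))

    def test_dropout_training_runs(self, small_encoded):
        cfg = AnsatzConfig(n_qubits=11, layers=2)
        res = train_vqc(cfg, small_encoded, QTrainConfig(max_epochs=3, seed=1),
                        dropout=DropoutConfig())
        assert res.epochs_run == 3

    def test_empty_training_set_rejected(self, small_encoded):
        cfg = AnsatzConfig(n_qubits=11, layers=1)
        with pytest.raises(ValueError):
            train_vqc(cfg, small_encoded, QTrainConfig(max_epochs=1),
                      train_index=np.array([], dtype=int))


class TestGradientStatistics:
    def test_reported_quantities(self, small_encoded):
        cfg = AnsatzConfig(n_qubits=11, layers=1)
        stats = gradient_statistics(cfg, small_encoded, n_inits=3, seed=4)
        assert stats["variance"] >= 0.0
        assert stats["mean_abs_gradient"] > 0.0
        again = gradient_statistics(cfg, small_encoded, n_inits=3, seed=4)
        assert stats == again
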