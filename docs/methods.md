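# Methods

## Statevector simulation

States are dense complex (or, where exactness permits, real) vectors of
length 2^n with qubit k stored as bit k of the amplitude index. A printed
ket label reads `q0 q1 … q_{n-1}` left to right with q0 the
least-significant bit, so amplitude vector (0.4, 0.4, 0.8, 0.2) is
0.4|00⟩ + 0.4|10⟩ + 0.8|01⟩ + 0.2|11⟩. This convention is fixed by the
2-qubit amplitude-encoding worked example the package reproduces, and all
label↔index conversions go through one pair of functions.

Gates are applied by tensor contraction on the reshaped state, never by
building 2^n×2^n matrices (the dense Kronecker construction exists only as
a ≤4-qubit test oracle). The supported set is RX/RY/RZ (the standard
half-angle Pauli rotations), CNOT and CZ. Because the whole classifier
family — RY encodings, RY ansatz rotations, CZ entanglers, Mottonen RY
cascades — has real matrices acting on real initial states, the training
path runs entirely in float64; a fused numba kernel handles the RY
contraction when numba is importable, with a pure-numpy fallback.
Simulation is exact and noiseless (infinite-shot limit): expectation values
are computed from amplitudes, and no shot sampling or noise channel exists
anywhere. Global phase is not normalized away; every observable quantity is
phase-invariant, and amplitude assertions in tests target real vectors.

Unitarity (norm preservation to 1e-10 across random circuits), agreement
with the dense-matrix oracle (1e-10, n ≤ 4) and the ZYZ Euler
decomposition property are enforced by tests.

### Mottonen state preparation

Arbitrary *real* unit vectors of length 2^k are prepared by a cascade of
uniformly controlled RY rotations, decomposed into RY+CNOT via the
Gray-code construction (O(4^n) gates). Interior-level angles come from
2·atan2 of sub-block norms; leaf-level angles use the signed pair values
2·atan2(b, a), which is what lets the RY-only cascade reach negative
amplitudes — needed because the amplitude register carries *standardized*
(signed) continuous features. The RZ phase stage of the general algorithm
is deliberately omitted: no complex-amplitude target exists in this
pipeline. Whether the original study carried signs in amplitudes or
shifted them away is not determinable from its description; signed
amplitudes are the choice here because they preserve the standardization
exactly. Correctness is tested by preparing random signed vectors
(amplitudes match to 1e-8) and by running the adjoint circuit back to
|0…0⟩.

## The classifier

### Circuit family

One ansatz layer on N qubits: RY(θ) on all N qubits; CZ on pairs
(0,1), (2,3), …; a second RY row; CZ on offset pairs (1,2), (3,4), …
restricted to the interior qubits. The second RY row defaults to qubits
0..N−2 (`exclude_last_only`), giving 2N−1 rotations per layer and a
(2N−1)·L total parameter count; the variant excluding both the first and
last qubits (2N−2 per layer) is a config switch. Both conventions are plausible
readings of this layer family's usual verbal description ("a second RY row
excluding the first and last qubits") versus its usual parameter count
((2N−1)L); the default follows the count, both are tested, and nothing
else in the pipeline depends on the choice.

Angle encoding uses 11 qubits (one per predictor, categoricals
integer-coded before scaling — the only reading that lands on exactly 11
qubits); the hybrid amplitude path uses 13 (3 amplitude + 10 basis). With
data re-uploading the encoding block precedes every ansatz layer;
re-uploading applies to angle encoding only, since repeating Mottonen
preparation would multiply circuit depth for no expressiveness gain.

The output is p = σ(Σᵢ⟨Zᵢ⟩ + b) over all qubits — a local measurement,
which also mitigates barren plateaus — and the decision rule on the
{−1, +1} label scale assigns +1 when p > 0.5 (ties, a measure-zero event,
go to −1). Training targets are kept on the {0,1} scale inside the
cross-entropy; the {−1,+1} shift exists only for the assignment rule, and
the two encodings are converted exactly.

### Gradients

`parameter_shift_gradient` implements the rule literally: each circuit
partial is evaluated at θ_k ± π/2 and combined as half the difference, then
chained through the sigmoid and the cross-entropy analytically. The
training loop uses `adjoint_gradient`, a reverse sweep that exploits
unitarity to obtain the *same* values (for Pauli rotations the analytic
derivative and the parameter-shift value are mathematically identical) in
O(1) state operations per gate instead of two circuit runs per parameter.
Tests pin the two routes to each other at 1e-10 and both to central finite
differences at 1e-5; dropped (masked) rotations have exactly zero gradient
in both.

### Training protocol

Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8 — conventional values, unstated in
the protocol being followed) on 10 batches of 64 per epoch, drawn without
replacement and reshuffled each epoch; a training set smaller than 640 is
partitioned with the short final batch kept. The learning rate starts at
0.01 and is halved after 50 epochs without improvement; training stops
after 100 such epochs; best-so-far parameters (by the monitored cost) are
returned. "Improvement" means a strict decrease of the epoch-mean training
loss by more than 1e-8, and the lr and stopping counters share that
monitored quantity. The quantum loop monitors the *training* cost — the
natural choice when the classical loop (below) is the one explicitly tied
to the test cost — and a test-cost monitor would be a one-line change.
Probabilities are clipped to [1e-12, 1−1e-12] inside the cross-entropy.

Initialization follows the stated recipe exactly: θ_k = 0.01·g_k with
g_k ~ Normal(μ=1, σ=1) — i.e. mean 0.01, sd 0.01 — and bias 0. The
non-zero mean is unusual for small-angle schemes, so a zero-mean
alternative is exposed in config, but the default reproduces the recipe as
written.

Quantum dropout resamples its mask at every optimization step: each layer
is independently selected with probability p_L = 0.1, and each trainable
rotation inside a selected layer is removed with probability p_G = 0.1,
for a per-rotation marginal of p = p_L·p_G = 0.01 (verified analytically
and by Monte Carlo in tests). Independent per-layer selection is chosen
over "exactly one layer per step" because it makes the stated product
marginal exact. Masks are disabled at evaluation time; no activation
rescaling applies (removing a rotation leaves a unitary circuit).

### Classical baselines

Perceptron and feedforward networks with Leaky-ReLU (α = 0.1), sigmoid
output, binary cross-entropy. He-normal weights and Xavier-uniform biases
for hidden networks; He-uniform weights and zero biases for the
perceptron. Dropout (rate 0.2) uses inverted scaling at train time — the
convention is a package choice, the protocol being mirrored is silent on
it. The schedule mirrors the quantum loop with lr₀ = 0.001, lr patience
100, stopping patience 500, monitored on the *test* cost exactly as the
protocol prescribes. **That monitoring choice leaks test information into
the stopping time and the best-epoch selection**; it is kept because
fidelity to the comparison protocol is the point of the baseline, and a
validation-split monitor is available via
`NNTrainConfig(monitor="validation")`.

The architecture grid (widths 4–64 in multiples of 4, depth 1–5,
non-increasing, ×2 for dropout) enumerates in the tens of thousands, so a
deterministic, seed-stable cap keeps desk-scale studies manageable (the
perceptron and the 3×52 reference network are always retained). The full
quantum grid expands to 54 configurations, and a row-exclusion list allows
narrower rosters — e.g. 46 configurations with the re-uploading+dropout
row excluded. The default classical input is a 13-column design (5 standardized
continuous; Sex/FastingBS/ExerciseAngina indicators; ChestPainType
drop-first one-hot; RestingECG and ST_Slope integer-coded and
standardized) — the width consistent with a 14-parameter perceptron floor —
with a full one-hot alternative in config.

## The synthetic cohort

The generator emulates the Heart Disease benchmark's *structure*, not its
joint distribution: continuous features are a Gaussian copula with the
benchmark's means/SDs clipped to the observed [min, max] (Age rounded to
years, Oldpeak to 0.1), with target correlations corr(Age, MaxHR) = −0.40
and corr(Age, Oldpeak) = +0.25 — the two robust patterns of the real
data; categoricals are independent multinomials at the public dataset's
approximate level frequencies; labels are Bernoulli from a logistic model
whose coefficients follow clinical direction (MaxHR negative; Oldpeak,
exertional angina, asymptomatic chest pain, flat/down ST slope positive)
and whose intercept is calibrated by root-finding so the expected
prevalence is 0.55. The default size is 918 records because that is the
only size consistent with the 643/275 70/30 split the pipeline reproduces
(the alternative figure of 914 that circulates for this dataset is
reachable via `n_records`). All preprocessing statistics (μ, σ, min, max)
are fitted on the training partition only and reused on the test side;
test values outside a fitted min-max range clip to the endpoints.

What the generator does *not* reproduce: interactions and nonlinearities
among predictors, the zero-inflation of Cholesterol in the real data,
dependence between categoricals and continuous features, and — most
consequentially — any nonlinear structure in the label. **The label model
is linear (logistic) by design**, so the Bayes-optimal decision boundary
is linear in the features. Passing desk-scale comparisons on this cohort
therefore demonstrates that the pipeline trains, generalizes and ranks
models sensibly — not that deeper circuits beat shallow ones here. In
measured runs the 1-layer angle VQC converges to ≈0.69 test accuracy while
the 2-layer circuit reaches *lower training loss* (0.52 vs 0.54) but ends
≈0.67 after its early accuracy peak decays — textbook variance from excess
capacity under a linear ground truth. The accuracy-vs-depth gains reported
on the real benchmark depend on structure this generator deliberately
omits, and the end-to-end study test documents exactly this discrepancy
when it fires.

## Desk-scale budgets

The full protocol (10 repeats of every grid configuration plus the
learning-curve sweep) is expressible but is a multi-day computation. The
bundled analyses and the end-to-end test use: the default 918-record
cohort, 3 seeds per configuration, at most 300 epochs with stopping
patience 60 and lr patience 30 (preserving the protocol's 2:1
patience ratio), and evaluation restricted to the roster that the
questions need. These sizes were chosen from the convergence behaviour of
the training loss on the default cohort.

## Numerical notes

- State norms are enforced to 1e-9 at construction; circuit execution
  preserves them to 1e-10 over random sequences.
- An all-zero continuous block in the hybrid encoder (possible only for
  degenerate input) falls back to |000⟩ rather than dividing by zero.
- Standardizing a zero-variance column and angle-scaling a constant column
  are errors, except that tiny-cohort angle encoding falls back to
  full-data scaling when a training column is constant.
- Subsample sizes use round-half-up; the train partition takes the ceiling.
- Per-run seeds derive from CRC32 of (config id, repeat, base seed), kept
  below 2^31.
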