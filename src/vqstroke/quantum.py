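"""From-scratch n-qubit statevector simulator and the 4-qubit variational circuit.

The register convention is **qubit 0 = most significant bit** of the basis
index: for ``n`` qubits, basis state ``|b0 b1 ... b_{n-1}>`` has index
``b0*2^{n-1} + ... + b_{n-1}``.  Gates are applied functionally — every
operation returns a new :class:`QuantumState`.

The variational circuit classifies a 4-dimensional standardized feature
vector: an angle encoding (Hadamard on every qubit followed by a data-dependent
phase rotation) is followed by three identical variational layers, each
``H(0) -> CNOT(0,1) -> RZ(theta_q) on every qubit``, for 3x4 = 12 trainable
angles, then Pauli-Z expectation readout on all four qubits.

``RZ`` here is the *phase gate* ``diag(1, e^{i theta})``.  It differs from the
textbook ``e^{-i theta Z / 2}`` only by a global phase, so every expectation
value (and hence the classifier) is identical under either convention; the
parameter-shift rule with shift ±π/2 and coefficient 1/2 is exact for both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "QuantumState",
    "VariationalParams",
    "CircuitOutput",
    "N_QUBITS",
    "N_LAYERS",
    "N_PARAMS",
    "init_state",
    "apply_hadamard",
    "apply_cnot",
    "apply_rz",
    "z_expectation",
    "sample_bitstrings",
    "encode_features",
    "variational_layer",
    "circuit_forward",
    "forward_z_batch",
    "predict_label",
    "parameter_shift_gradient",
]

N_QUBITS = 4
N_LAYERS = 3
N_PARAMS = N_LAYERS * N_QUBITS  # 12 trainable angles

_MAX_QUBITS = 20  # statevector memory doubles per qubit; 2^20 amplitudes is the cap

_H = np.array([[1.0, 1.0], [1.0, -1.0]], dtype=complex) / np.sqrt(2.0)

_NORM_TOL = 1e-12


@dataclass(frozen=True)
class QuantumState:
    """Pure state of ``n_qubits`` qubits as a unit-norm complex amplitude vector."""

    n_qubits: int
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        amps = np.asarray(self.amplitudes, dtype=complex)
        if amps.shape != (2**self.n_qubits,):
            raise ValueError(
                f"amplitude vector has shape {amps.shape}, "
                f"expected ({2 ** self.n_qubits},) for {self.n_qubits} qubits"
            )
        object.__setattr__(self, "amplitudes", amps)

    @property
    def norm_sq(self) -> float:
        return float(np.sum(np.abs(self.amplitudes) ** 2))


@dataclass(frozen=True)
class VariationalParams:
    """The 12 trainable rotation angles, indexed (layer 0..2, qubit 0..3)."""

    theta: np.ndarray  # shape (3, 4), radians

    def __post_init__(self) -> None:
        th = np.asarray(self.theta, dtype=float)
        if th.size != N_PARAMS:
            raise ValueError(f"expected {N_PARAMS} angles, got {th.size}")
        th = th.reshape(N_LAYERS, N_QUBITS)
        if not np.all(np.isfinite(th)):
            raise ValueError("angles must be finite")
        object.__setattr__(self, "theta", th)

    @property
    def flat(self) -> np.ndarray:
        """Layer-major flattened view, length 12."""
        return self.theta.reshape(-1)

    def with_shift(self, k: int, delta: float) -> "VariationalParams":
        """Copy with angle ``k`` (layer-major index) shifted by ``delta``."""
        if not 0 <= k < N_PARAMS:
            raise ValueError(f"parameter index {k} out of range [0, {N_PARAMS})")
        flat = self.flat.copy()
        flat[k] += delta
        return VariationalParams(flat)


@dataclass(frozen=True)
class CircuitOutput:
    """Readout of the classifier circuit.

    ``p_stroke`` is the fixed readout map ``(1 - mean(z)) / 2``: the mean
    Z-expectation is +1 when every qubit reads 0 (confident "normal") and -1
    when every qubit reads 1 (confident "stroke").
    """

    z_expectations: np.ndarray  # 4 reals in [-1, 1]
    p_stroke: float = field(init=False)

    def __post_init__(self) -> None:
        z = np.asarray(self.z_expectations, dtype=float)
        if z.shape != (N_QUBITS,):
            raise ValueError(f"expected {N_QUBITS} z-expectations, got shape {z.shape}")
        object.__setattr__(self, "z_expectations", z)
        object.__setattr__(self, "p_stroke", float((1.0 - z.mean()) / 2.0))


# ---------------------------------------------------------------------------
# batched amplitude kernels (last axis = 2^n); shared by the public gate ops
# and the vectorised training forward pass


def _apply_single_qubit(amp: np.ndarray, n: int, q: int, mat: np.ndarray) -> np.ndarray:
    """Apply a 2x2 unitary to qubit ``q`` of amplitudes with last axis 2^n."""
    lead = amp.shape[:-1]
    t = amp.reshape(lead + (2,) * n)
    axis = len(lead) + q
    t = np.moveaxis(t, axis, -1)
    t = t @ mat.T
    t = np.moveaxis(t, -1, axis)
    return np.ascontiguousarray(t.reshape(lead + (2**n,)))


def _apply_cnot_amp(amp: np.ndarray, n: int, control: int, target: int) -> np.ndarray:
    lead = amp.shape[:-1]
    t = amp.reshape(lead + (2,) * n).copy()
    c_ax = len(lead) + control
    t_ax = len(lead) + target
    t = np.moveaxis(t, (c_ax, t_ax), (-2, -1))
    # flip target bit on the control=1 slab
    t[..., 1, :] = t[..., 1, ::-1]
    t = np.moveaxis(t, (-2, -1), (c_ax, t_ax))
    return np.ascontiguousarray(t.reshape(lead + (2**n,)))


def _apply_rz_amp(amp: np.ndarray, n: int, q: int, theta) -> np.ndarray:
    """Phase gate diag(1, e^{i theta}); ``theta`` may broadcast over lead axes."""
    lead = amp.shape[:-1]
    t = amp.reshape(lead + (2,) * n).copy()
    axis = len(lead) + q
    t = np.moveaxis(t, axis, -1)
    phase = np.exp(1j * np.asarray(theta, dtype=float))
    if phase.ndim > 0:
        # per-sample angles: broadcast over the remaining qubit axes
        phase = phase.reshape(phase.shape + (1,) * (n - 1))
    t[..., 1] = t[..., 1] * phase
    t = np.moveaxis(t, -1, axis)
    return np.ascontiguousarray(t.reshape(lead + (2**n,)))


def _z_expectation_amp(amp: np.ndarray, n: int, q: int) -> np.ndarray:
    """<Z_q> = P(bit q = 0) - P(bit q = 1), batched over lead axes."""
    lead = amp.shape[:-1]
    t = np.abs(amp.reshape(lead + (2,) * n)) ** 2
    axis = len(lead) + q
    t = np.moveaxis(t, axis, -1)
    t = t.reshape(lead + (-1, 2)).sum(axis=-2)
    return t[..., 0] - t[..., 1]


def _check_qubit(n: int, q: int) -> None:
    if not 0 <= q < n:
        raise ValueError(f"qubit index {q} out of range for {n}-qubit register")


# ---------------------------------------------------------------------------
# public gate operations


def init_state(n_qubits: int) -> QuantumState:
    """All-qubits-ground state |0...0> of an ``n_qubits`` register.

    ``n_qubits`` is capped at 20: the amplitude vector has 2^n entries, so the
    classical cost of simulation grows exponentially with register width.
    """
    if not 1 <= n_qubits <= _MAX_QUBITS:
        raise ValueError(
            f"n_qubits must be in [1, {_MAX_QUBITS}] "
            "(statevector simulation cost is exponential in qubit count)"
        )
    amps = np.zeros(2**n_qubits, dtype=complex)
    amps[0] = 1.0
    return QuantumState(n_qubits, amps)


def apply_hadamard(state: QuantumState, q: int) -> QuantumState:
    """Hadamard on qubit ``q``: (1/sqrt 2)[[1,1],[1,-1]]."""
    _check_qubit(state.n_qubits, q)
    return QuantumState(
        state.n_qubits, _apply_single_qubit(state.amplitudes, state.n_qubits, q, _H)
    )


def apply_cnot(state: QuantumState, control: int, target: int) -> QuantumState:
    """CNOT: flip the target bit on every amplitude whose control bit is 1."""
    _check_qubit(state.n_qubits, control)
    _check_qubit(state.n_qubits, target)
    if control == target:
        raise ValueError("control and target qubits must differ")
    return QuantumState(
        state.n_qubits,
        _apply_cnot_amp(state.amplitudes, state.n_qubits, control, target),
    )


def apply_rz(state: QuantumState, q: int, theta: float) -> QuantumState:
    """Phase rotation diag(1, e^{i theta}) on qubit ``q``."""
    _check_qubit(state.n_qubits, q)
    if not np.isfinite(theta):
        raise ValueError("theta must be finite")
    return QuantumState(
        state.n_qubits, _apply_rz_amp(state.amplitudes, state.n_qubits, q, theta)
    )


def z_expectation(state: QuantumState, q: int) -> float:
    """Pauli-Z expectation of qubit ``q``; +1 on |0>, -1 on |1>."""
    _check_qubit(state.n_qubits, q)
    return float(_z_expectation_amp(state.amplitudes, state.n_qubits, q))


def sample_bitstrings(
    state: QuantumState, n_shots: int, rng: np.random.Generator
) -> list[str]:
    """Born-rule measurement: i.i.d. bitstring samples with P(b) = |amp_b|^2."""
    if n_shots < 1:
        raise ValueError("n_shots must be >= 1")
    probs = np.abs(state.amplitudes) ** 2
    probs = probs / probs.sum()  # guard rounding at the 1e-16 level
    idx = rng.choice(len(probs), size=n_shots, p=probs)
    n = state.n_qubits
    return [format(i, f"0{n}b") for i in idx]


# ---------------------------------------------------------------------------
# the classifier circuit


def encode_features(x: np.ndarray) -> QuantumState:
    """Angle-encode 4 standardized features into the 4-qubit register.

    Each feature is clipped to [-3, 3] (3 standard deviations), then
    ``H`` on every qubit followed by ``RZ(pi * x_q / 3)`` on qubit ``q``.
    The Hadamard first is essential: a phase rotation on a basis state is a
    global phase, but on the superposition (|0>+|1>)/sqrt 2 it moves the state
    along the equator of the Bloch sphere, so the encoding is injective on the
    clipped range.
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    if x.size != N_QUBITS:
        raise ValueError(f"expected {N_QUBITS} features, got {x.size}")
    x = np.clip(x, -3.0, 3.0)
    state = init_state(N_QUBITS)
    for q in range(N_QUBITS):
        state = apply_hadamard(state, q)
    for q in range(N_QUBITS):
        state = apply_rz(state, q, np.pi * x[q] / 3.0)
    return state


def variational_layer(state: QuantumState, theta_layer: np.ndarray) -> QuantumState:
    """One variational layer: H(0); CNOT(0 -> 1); RZ(theta[q]) on each qubit."""
    theta_layer = np.asarray(theta_layer, dtype=float).reshape(-1)
    if theta_layer.size != N_QUBITS:
        raise ValueError(f"expected {N_QUBITS} angles per layer, got {theta_layer.size}")
    state = apply_hadamard(state, 0)
    state = apply_cnot(state, 0, 1)
    for q in range(N_QUBITS):
        state = apply_rz(state, q, theta_layer[q])
    return state


def circuit_forward(x: np.ndarray, params: VariationalParams) -> CircuitOutput:
    """Full forward pass: encode, 3 variational layers, Z readout on all qubits."""
    state = encode_features(x)
    for layer in range(N_LAYERS):
        state = variational_layer(state, params.theta[layer])
    z = np.array([z_expectation(state, q) for q in range(N_QUBITS)])
    return CircuitOutput(z)


def forward_z_batch(X: np.ndarray, params: VariationalParams) -> np.ndarray:
    """Vectorised forward pass for a batch of feature vectors.

    Parameters
    ----------
    X : array of shape (m, 4)
        Standardized feature vectors (clipped to [-3, 3] internally).

    Returns
    -------
    array of shape (m, 4) with the per-qubit Z expectations; row i equals
    ``circuit_forward(X[i], params).z_expectations``.
    """
    X = np.clip(np.asarray(X, dtype=float), -3.0, 3.0)
    if X.ndim != 2 or X.shape[1] != N_QUBITS:
        raise ValueError(f"X must have shape (m, {N_QUBITS})")
    m = X.shape[0]
    amp = np.zeros((m, 2**N_QUBITS), dtype=complex)
    amp[:, 0] = 1.0
    for q in range(N_QUBITS):
        amp = _apply_single_qubit(amp, N_QUBITS, q, _H)
    for q in range(N_QUBITS):
        amp = _apply_rz_amp(amp, N_QUBITS, q, np.pi * X[:, q] / 3.0)
    for layer in range(N_LAYERS):
        amp = _apply_single_qubit(amp, N_QUBITS, 0, _H)
        amp = _apply_cnot_amp(amp, N_QUBITS, 0, 1)
        for q in range(N_QUBITS):
            amp = _apply_rz_amp(amp, N_QUBITS, q, params.theta[layer, q])
    return np.stack(
        [_z_expectation_amp(amp, N_QUBITS, q) for q in range(N_QUBITS)], axis=1
    )


def p_stroke_from_z(z: np.ndarray) -> np.ndarray:
    """Readout map (1 - mean z)/2 applied along the last axis."""
    z = np.asarray(z, dtype=float)
    return (1.0 - z.mean(axis=-1)) / 2.0


def predict_label(out: CircuitOutput) -> int:
    """Majority vote over qubits: bit_q = 1 iff <Z_q> < 0.

    Label is stroke (1) when >= 3 of 4 bits vote stroke, normal (0) when <= 1
    does; a 2-2 tie is broken by the probability readout (stroke iff
    ``p_stroke >= 0.5``).
    """
    bits = (out.z_expectations < 0).astype(int)
    votes = int(bits.sum())
    if votes >= 3:
        return 1
    if votes <= 1:
        return 0
    return 1 if out.p_stroke >= 0.5 else 0


def parameter_shift_gradient(
    x: np.ndarray, params: VariationalParams, k: int, loss_fn
) -> float:
    """Exact gradient of ``loss_fn(circuit_forward(x, .))`` w.r.t. angle ``k``.

    Uses the parameter-shift rule ``[L(theta_k + pi/2) - L(theta_k - pi/2)]/2``,
    exact for the phase-gate family diag(1, e^{i theta}) (eigenvalue gap 1 up
    to global phase) whenever ``loss_fn`` is a *linear* readout of the circuit
    expectations — e.g. ``lambda out: out.p_stroke`` or any fixed combination
    of ``out.z_expectations``.  For a loss that is nonlinear in the
    expectations (such as cross-entropy), differentiate the loss analytically
    in the probability and chain it with this rule applied to ``p_stroke``;
    the training loop in :mod:`vqstroke.model` does exactly that.
    """
    if not 0 <= k < N_PARAMS:
        raise ValueError(f"parameter index {k} out of range [0, {N_PARAMS})")
    plus = loss_fn(circuit_forward(x, params.with_shift(k, np.pi / 2)))
    minus = loss_fn(circuit_forward(x, params.with_shift(k, -np.pi / 2)))
    return float((plus - minus) / 2.0)


def p_stroke_shift_gradients(X: np.ndarray, params: VariationalParams) -> np.ndarray:
    """Batched parameter-shift gradients of p_stroke.

    Returns an array of shape (m, 12): entry (i, k) is d p_stroke(X[i]) /
    d theta_k, computed exactly from two shifted batched forward passes per
    parameter (24 passes total).
    """
    m = np.asarray(X).shape[0]
    grads = np.empty((m, N_PARAMS))
    for k in range(N_PARAMS):
        p_plus = p_stroke_from_z(forward_z_batch(X, params.with_shift(k, np.pi / 2)))
        p_minus = p_stroke_from_z(forward_z_batch(X, params.with_shift(k, -np.pi / 2)))
        grads[:, k] = (p_plus - p_minus) / 2.0
    return grads
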