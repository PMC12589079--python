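"""Statevector simulator: gate algebra, circuit oracle equivalence,
parameter-shift gradients, measurement."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vqstroke import quantum as q
from vqstroke.quantum import (
    CircuitOutput,
    QuantumState,
    VariationalParams,
    apply_cnot,
    apply_hadamard,
    apply_rz,
    circuit_forward,
    encode_features,
    forward_z_batch,
    init_state,
    parameter_shift_gradient,
    predict_label,
    sample_bitstrings,
    variational_layer,
    z_expectation,
)

H = np.array([[1, 1], [1, -1]], dtype=complex) / np.sqrt(2)


def kron_chain(mats):
    out = mats[0]
    for m in mats[1:]:
        out = np.kron(out, m)
    return out


def dense_single(mat, qpos, n):
    ops = [np.eye(2, dtype=complex)] * n
    ops[qpos] = mat
    return kron_chain(ops)


def dense_cnot(control, target, n):
    """Permutation matrix for CNOT under the qubit-0-MSB index convention."""
    dim = 2**n
    U = np.zeros((dim, dim), dtype=complex)
    for i in range(dim):
        bits = [(i >> (n - 1 - k)) & 1 for k in range(n)]
        if bits[control]:
            bits[target] ^= 1
        j = sum(b << (n - 1 - k) for k, b in enumerate(bits))
        U[j, i] = 1.0
    return U


def dense_rz(theta):
    return np.diag([1.0, np.exp(1j * theta)]).astype(complex)


def dense_circuit_unitary(x, theta):
    """Independent 16x16 Kronecker-product oracle for the full circuit."""
    xc = np.clip(np.asarray(x, dtype=float), -3, 3)
    U = np.eye(16, dtype=complex)
    for qq in range(4):
        U = dense_single(H, qq, 4) @ U
    for qq in range(4):
        U = dense_single(dense_rz(np.pi * xc[qq] / 3), qq, 4) @ U
    for layer in range(3):
        U = dense_single(H, 0, 4) @ U
        U = dense_cnot(0, 1, 4) @ U
        for qq in range(4):
            U = dense_single(dense_rz(theta[layer, qq]), qq, 4) @ U
    return U


def random_state(n, rng):
    amps = rng.normal(size=2**n) + 1j * rng.normal(size=2**n)
    return QuantumState(n, amps / np.linalg.norm(amps))


def basis(n, idx):
    amps = np.zeros(2**n, dtype=complex)
    amps[idx] = 1.0
    return QuantumState(n, amps)


class TestInitState:
    def test_four_qubit_ground_state(self):
        s = init_state(4)
        assert s.amplitudes.shape == (16,)
        assert s.amplitudes[0] == 1.0 and np.all(s.amplitudes[1:] == 0)

    def test_single_qubit(self):
        assert np.array_equal(init_state(1).amplitudes, [1, 0])

    @pytest.mark.parametrize("n", [0, 21, -3])
    def test_register_width_bounds(self, n):
        with pytest.raises(ValueError):
            init_state(n)


class TestGates:
    def test_hadamard_on_ground_state(self):
        s = apply_hadamard(init_state(1), 0)
        assert np.allclose(s.amplitudes, [0.70710678, 0.70710678], atol=1e-8)

    def test_hadamard_on_excited_state_standard_sign(self):
        s = apply_hadamard(basis(1, 1), 0)
        assert np.allclose(s.amplitudes, [0.70710678, -0.70710678], atol=1e-8)

    def test_hadamard_squared_is_identity(self, rng):
        s = random_state(3, rng)
        out = apply_hadamard(apply_hadamard(s, 1), 1)
        assert np.allclose(out.amplitudes, s.amplitudes, atol=1e-12)

    def test_cnot_truth_table(self):
        # states |00>, |01>, |10>, |11> at indices 0..3 (qubit 0 = MSB)
        expected = {0: 0, 1: 1, 2: 3, 3: 2}
        for i, j in expected.items():
            out = apply_cnot(basis(2, i), 0, 1)
            assert np.allclose(out.amplitudes, basis(2, j).amplitudes, atol=1e-15)

    def test_cnot_is_involution(self, rng):
        s = random_state(4, rng)
        out = apply_cnot(apply_cnot(s, 2, 0), 2, 0)
        assert np.allclose(out.amplitudes, s.amplitudes, atol=1e-15)

    def test_cnot_rejects_equal_control_target(self):
        with pytest.raises(ValueError):
            apply_cnot(init_state(2), 1, 1)

    def test_rz_zero_angle_is_identity(self, rng):
        s = random_state(2, rng)
        assert np.allclose(apply_rz(s, 0, 0.0).amplitudes, s.amplitudes, atol=1e-15)

    def test_rz_pi_flips_excited_amplitude_sign(self):
        out = apply_rz(basis(1, 1), 0, np.pi)
        assert np.allclose(out.amplitudes, [0, -1], atol=1e-12)

    def test_rz_quarter_turn_on_superposition(self):
        s = apply_hadamard(init_state(1), 0)
        out = apply_rz(s, 0, np.pi / 2)
        assert np.allclose(out.amplitudes, [0.70710678, 0.70710678j], atol=1e-8)

    @given(st.floats(-6, 6), st.floats(-6, 6))
    def test_rz_additivity(self, a, b):
        rng = np.random.default_rng(77)
        s = random_state(2, rng)
        one = apply_rz(apply_rz(s, 1, a), 1, b)
        both = apply_rz(s, 1, a + b)
        assert np.allclose(one.amplitudes, both.amplitudes, atol=1e-12)

    def test_norm_conserved_through_random_gate_sequences(self, rng):
        s = random_state(4, rng)
        for _ in range(60):
            choice = rng.integers(3)
            if choice == 0:
                s = apply_hadamard(s, int(rng.integers(4)))
            elif choice == 1:
                a, b = rng.choice(4, size=2, replace=False)
                s = apply_cnot(s, int(a), int(b))
            else:
                s = apply_rz(s, int(rng.integers(4)), float(rng.normal()))
            assert abs(s.norm_sq - 1.0) < 1e-12


class TestMeasurement:
    def test_z_eigenvalues_on_basis_states(self):
        assert z_expectation(basis(1, 0), 0) == 1.0
        assert z_expectation(basis(1, 1), 0) == -1.0

    def test_z_zero_on_equal_superposition(self):
        s = apply_hadamard(init_state(1), 0)
        assert z_expectation(s, 0) == pytest.approx(0.0, abs=1e-12)

    def test_sampling_deterministic_state(self, rng):
        samples = sample_bitstrings(init_state(4), 50, rng)
        assert samples == ["0000"] * 50

    def test_sampling_matches_born_probabilities(self, rng):
        s = apply_hadamard(init_state(1), 0)
        samples = sample_bitstrings(s, 10_000, rng)
        frac_one = np.mean([b == "1" for b in samples])
        assert abs(frac_one - 0.5) < 0.02  # 3-sigma binomial bound at n=10k

    def test_sampling_seeded_determinism(self):
        s = apply_hadamard(init_state(2), 1)
        a = sample_bitstrings(s, 100, np.random.default_rng(9))
        b = sample_bitstrings(s, 100, np.random.default_rng(9))
        assert a == b


class TestEncodingAndLayers:
    def test_zero_features_give_uniform_superposition(self):
        s = encode_features(np.zeros(4))
        assert np.allclose(s.amplitudes, np.full(16, 0.25), atol=1e-12)
        for qq in range(4):
            assert z_expectation(s, qq) == pytest.approx(0.0, abs=1e-12)

    def test_encoding_is_norm_preserving(self, rng):
        for _ in range(10):
            s = encode_features(rng.normal(size=4) * 2)
            assert abs(s.norm_sq - 1.0) < 1e-12

    def test_saturated_feature_matches_explicit_gates(self):
        s = encode_features(np.array([3.0, 0, 0, 0]))
        ref = init_state(4)
        for qq in range(4):
            ref = apply_hadamard(ref, qq)
        ref = apply_rz(ref, 0, np.pi)
        assert np.allclose(s.amplitudes, ref.amplitudes, atol=1e-12)

    def test_features_clip_beyond_three_sigma(self):
        assert np.allclose(
            encode_features(np.array([5.0, 0, 0, 0])).amplitudes,
            encode_features(np.array([3.0, 0, 0, 0])).amplitudes,
            atol=1e-15,
        )

    def test_zero_angle_layer_on_ground_state(self):
        out = variational_layer(init_state(4), np.zeros(4))
        expected = np.zeros(16, dtype=complex)
        expected[0] = expected[12] = 1 / np.sqrt(2)  # (|0000> + |1100>)/sqrt 2
        assert np.allclose(out.amplitudes, expected, atol=1e-12)

    def test_layer_rejects_wrong_angle_count(self):
        with pytest.raises(ValueError):
            variational_layer(init_state(4), np.zeros(3))

    def test_params_require_exactly_twelve_angles(self):
        with pytest.raises(ValueError):
            VariationalParams(np.zeros(11))
        assert VariationalParams(np.zeros(12)).flat.shape == (12,)


class TestCircuitForward:
    def test_matches_dense_unitary_oracle_on_random_draws(self, rng):
        psi0 = np.zeros(16, dtype=complex)
        psi0[0] = 1.0
        for _ in range(100):
            x = rng.normal(size=4) * 2
            theta = rng.normal(size=(3, 4))
            psi = dense_circuit_unitary(x, theta) @ psi0
            zs = np.array([z_expectation(QuantumState(4, psi), qq) for qq in range(4)])
            out = circuit_forward(x, VariationalParams(theta))
            assert np.max(np.abs(out.z_expectations - zs)) < 1e-10

    def test_batched_forward_equals_per_sample(self, rng):
        X = rng.normal(size=(7, 4))
        params = VariationalParams(rng.normal(size=12))
        Z = forward_z_batch(X, params)
        for i in range(7):
            assert np.allclose(
                Z[i], circuit_forward(X[i], params).z_expectations, atol=1e-12
            )

    def test_readout_map_and_probability_range(self, rng):
        out = circuit_forward(rng.normal(size=4), VariationalParams(rng.normal(size=12)))
        assert 0.0 <= out.p_stroke <= 1.0
        assert out.p_stroke == pytest.approx((1 - out.z_expectations.mean()) / 2)

    def test_two_pi_periodic_in_every_angle(self, rng):
        x = rng.normal(size=4)
        theta = rng.normal(size=12)
        base = circuit_forward(x, VariationalParams(theta))
        for k in range(12):
            shifted = theta.copy()
            shifted[k] += 2 * np.pi
            out = circuit_forward(x, VariationalParams(shifted))
            assert np.allclose(out.z_expectations, base.z_expectations, atol=1e-10)


class TestPredictLabel:
    @pytest.mark.parametrize(
        "z,expected",
        [
            ((-0.2, -0.1, 0.3, -0.4), 1),  # 3 stroke votes
            ((1, 1, 1, 1), 0),
            ((-0.6, -0.6, 0.1, 0.1), 1),  # 2-2 tie, mean z < 0 => p >= 0.5
            ((0.6, 0.6, -0.1, -0.1), 0),  # 2-2 tie, mean z > 0
        ],
    )
    def test_majority_vote_with_tie_rule(self, z, expected):
        assert predict_label(CircuitOutput(np.array(z, dtype=float))) == expected


class TestParameterShift:
    def test_matches_finite_differences_on_random_draws(self, rng):
        """Exact shift-rule gradient of the probability readout vs. central
        finite differences, 50 random (x, theta, k) draws."""
        read = lambda out: out.p_stroke
        h = 1e-5
        for _ in range(50):
            x = rng.normal(size=4)
            params = VariationalParams(rng.normal(size=12))
            k = int(rng.integers(12))
            g = parameter_shift_gradient(x, params, k, read)
            fp = read(circuit_forward(x, params.with_shift(k, h)))
            fm = read(circuit_forward(x, params.with_shift(k, -h)))
            assert abs(g - (fp - fm) / (2 * h)) < 1e-6

    def test_pinned_qubit_angles_have_zero_gradient(self, rng):
        # qubits 2 and 3 see only diagonal gates after encoding: <Z> is pinned
        x = rng.normal(size=4)
        params = VariationalParams(rng.normal(size=12))
        for layer in range(3):
            for qq in (2, 3):
                k = layer * 4 + qq
                g = parameter_shift_gradient(x, params, k, lambda o: o.p_stroke)
                assert abs(g) < 1e-12

    def test_gradient_two_pi_periodic(self, rng):
        x = rng.normal(size=4)
        theta = rng.normal(size=12)
        k = 1
        g1 = parameter_shift_gradient(x, VariationalParams(theta), k, lambda o: o.p_stroke)
        theta[k] += 2 * np.pi
        g2 = parameter_shift_gradient(x, VariationalParams(theta), k, lambda o: o.p_stroke)
        assert g1 == pytest.approx(g2, abs=1e-10)

    def test_rejects_bad_parameter_index(self, rng):
        with pytest.raises(ValueError):
            parameter_shift_gradient(
                np.zeros(4), VariationalParams(np.zeros(12)), 12, lambda o: o.p_stroke
            )


def test_circuit_json_roundtrip(tmp_path, rng):
    """Circuit parameters serialize to JSON and round-trip exactly."""
    import json

    params = VariationalParams(rng.normal(size=12))
    spec = {
        "n_qubits": 4,
        "layers": 3,
        "theta": params.flat.tolist(),
        "encoding": "hadamard+rz(pi*x/3)",
    }
    path = tmp_path / "circuit.json"
    path.write_text(json.dumps(spec))
    loaded = json.loads(path.read_text())
    assert loaded == spec
    assert np.array_equal(np.array(loaded["theta"]), params.flat)
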