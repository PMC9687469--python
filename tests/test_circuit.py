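import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import qmetric as qm
from qmetric import EmbeddingConfig, QuantumParams, TwoQubitState

from oracles import (
    embed_closed_form,
    embed_unitary,
    rx_pair_on_00_closed_form,
    ry_pair_closed_form,
    u_rx_pair,
    u_ry_pair,
    u_zz,
    zz_closed_form,
)

angles = st.floats(min_value=-10.0, max_value=10.0, allow_nan=False)


def _random_state(seed):
    gen = np.random.default_rng(seed)
    v = gen.normal(size=4) + 1j * gen.normal(size=4)
    return TwoQubitState(v / np.linalg.norm(v))


class TestGates:
    def test_zero_angles_are_identity_or_global_phase(self):
        s = TwoQubitState.basis00()
        assert np.allclose(qm.rx_pair(s, 0.0, 0.0).amplitudes, s.amplitudes)
        assert np.allclose(qm.zz(s, 0.0).amplitudes, s.amplitudes)
        assert np.allclose(qm.ry_pair(s, 0.0, 0.0).amplitudes, s.amplitudes)

    def test_encoding_on_00_matches_closed_form(self, rng):
        for _ in range(50):
            x1, x2 = rng.uniform(-6, 6, size=2)
            got = qm.rx_pair(TwoQubitState.basis00(), x1, x2).amplitudes
            assert np.allclose(got, rx_pair_on_00_closed_form(x1, x2), atol=1e-12)

    def test_zz_applies_parity_phases_and_preserves_overlaps(self, rng):
        s = _random_state(0)
        theta = 1.234
        got = qm.zz(s, theta).amplitudes
        assert np.allclose(got, zz_closed_form(s.amplitudes, theta), atol=1e-12)
        # |00> only picks up a global phase; overlaps are untouched
        g0 = qm.zz(TwoQubitState.basis00(), theta).amplitudes
        assert np.allclose(g0, np.exp(-0.5j * theta) * TwoQubitState.basis00().amplitudes)
        other = _random_state(1)
        before = qm.overlap(s, other)
        after = qm.overlap(qm.zz(s, theta), qm.zz(other, theta))
        assert after == pytest.approx(before, abs=1e-12)

    def test_ry_closed_form_and_forced_point(self, rng):
        # analytically forced point: Ry(pi/2) (x) Ry(0) on |00> gives cos(pi/4)
        got = qm.ry_pair(TwoQubitState.basis00(), np.pi / 2, 0.0).amplitudes
        assert got[0] == pytest.approx(np.sqrt(2) / 2)
        for seed in range(30):
            s = _random_state(seed)
            ta, tb = rng.uniform(-6, 6, size=2)
            assert np.allclose(
                qm.ry_pair(s, ta, tb).amplitudes,
                ry_pair_closed_form(s.amplitudes, ta, tb),
                atol=1e-12,
            )

    @pytest.mark.parametrize(
        "gate,oracle",
        [
            (lambda s, a, b: qm.rx_pair(s, a, b), u_rx_pair),
            (lambda s, a, b: qm.zz(s, a), lambda a, b: u_zz(a)),
            (lambda s, a, b: qm.ry_pair(s, a, b), u_ry_pair),
        ],
        ids=["rx_pair", "zz", "ry_pair"],
    )
    def test_each_gate_matches_matrix_exponential_oracle(self, gate, oracle, rng):
        for seed in range(40):
            s = _random_state(seed + 100)
            a, b = rng.uniform(-7, 7, size=2)
            expected = oracle(a, b) @ s.amplitudes
            assert np.allclose(gate(s, a, b).amplitudes, expected, atol=1e-12)


class TestEmbed:
    def test_all_zero_inputs_give_00(self):
        s = qm.embed(0.0, 0.0, QuantumParams(np.zeros(12)))
        assert np.allclose(np.abs(s.amplitudes), [1, 0, 0, 0], atol=1e-12)

    def test_default_trajectory_has_14_stages(self):
        params = QuantumParams(np.linspace(0.1, 1.2, 12))
        stages = qm.embed(0.3, -0.4, params, return_trajectory=True)
        assert len(stages) == 14
        assert EmbeddingConfig().n_stages == 14
        no_final = EmbeddingConfig(final_encoding=False)
        stages13 = qm.embed(0.3, -0.4, params, no_final, return_trajectory=True)
        assert len(stages13) == 13

    def test_wrong_parameter_count_rejected(self):
        with pytest.raises(ValueError, match="12 circuit angles"):
            qm.embed(0.0, 0.0, QuantumParams(np.zeros(11)))

    def test_matches_unitary_product_oracle(self, rng):
        for _ in range(100):
            x1, x2 = rng.uniform(-5, 5, size=2)
            th = rng.uniform(0, 2 * np.pi, size=12)
            got = qm.embed(x1, x2, QuantumParams(th)).amplitudes
            want = embed_unitary(x1, x2, th) @ [1, 0, 0, 0]
            assert np.allclose(got, want, atol=1e-10)

    def test_matches_closed_form_recursion(self, rng):
        for _ in range(100):
            x1, x2 = rng.uniform(-5, 5, size=2)
            th = rng.uniform(0, 2 * np.pi, size=12)
            got = qm.embed(x1, x2, QuantumParams(th)).amplitudes
            assert np.allclose(got, embed_closed_form(x1, x2, th), atol=1e-10)

    def test_batch_agrees_with_single_and_tangents_with_differences(self, rng):
        th = rng.uniform(0, 2 * np.pi, size=12)
        inputs = rng.uniform(-3, 3, size=(8, 2))
        batch = qm.embed_batch(inputs, th)
        for i, (x1, x2) in enumerate(inputs):
            single = qm.embed(x1, x2, QuantumParams(th)).amplitudes
            assert np.allclose(batch[i], single, atol=1e-12)
        # tangents = directional derivatives of the state, central differences
        states, tan = qm.embed_batch(inputs, th, with_tangents=True)
        assert np.allclose(states, batch, atol=1e-14)
        h = 1e-6
        for slot in range(2 + 12):
            if slot < 2:
                plus = inputs.copy(); plus[:, slot] += h
                minus = inputs.copy(); minus[:, slot] -= h
                fd = (qm.embed_batch(plus, th) - qm.embed_batch(minus, th)) / (2 * h)
            else:
                tp = th.copy(); tp[slot - 2] += h
                tm = th.copy(); tm[slot - 2] -= h
                fd = (qm.embed_batch(inputs, tp) - qm.embed_batch(inputs, tm)) / (2 * h)
            assert np.allclose(tan[:, slot], fd, atol=1e-8)


class TestInvariants:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(x1=angles, x2=angles, seed=st.integers(0, 10_000))
    def test_embedding_preserves_norm(self, x1, x2, seed):
        th = np.random.default_rng(seed).uniform(0, 2 * np.pi, size=12)
        s = qm.embed(x1, x2, QuantumParams(th))
        assert abs(np.linalg.norm(s.amplitudes) - 1.0) < 1e-12

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(phase=angles, seed=st.integers(0, 10_000))
    def test_overlap_ignores_global_phase(self, phase, seed):
        a = _random_state(seed)
        b = _random_state(seed + 1)
        rotated = TwoQubitState(np.exp(1j * phase) * a.amplitudes)
        assert qm.overlap(rotated, b) == pytest.approx(qm.overlap(a, b), abs=1e-12)

    def test_four_pi_periodicity_of_overlaps(self, rng):
        th = rng.uniform(0, 2 * np.pi, size=12)
        params = QuantumParams(th)
        ref = qm.embed(0.7, -0.2, params)
        shifted = qm.embed(0.7 + 4 * np.pi, -0.2, params)
        probe = _random_state(3)
        assert qm.overlap(shifted, probe) == pytest.approx(qm.overlap(ref, probe), abs=1e-10)

    def test_state_normalization_enforced(self):
        with pytest.raises(ValueError, match="not normalized"):
            TwoQubitState(np.array([1.0, 1.0, 0.0, 0.0]))

    def test_config_validation(self):
        with pytest.raises(ValueError, match="n_layers"):
            EmbeddingConfig(n_layers=0)
        with pytest.raises(ValueError, match="3 trainable angles"):
            EmbeddingConfig(params_per_layer=2)
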