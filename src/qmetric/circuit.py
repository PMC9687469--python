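"""Exact statevector simulation of the two-qubit embedding circuit.

The trainable feature map acts on two qubits.  One *ansatz layer* is

    Rx(x1) (x) Rx(x2)   -- data encoding, one angle per qubit
    ZZ(theta)           -- trainable entangler
    Ry(theta_a) (x) Ry(theta_b)  -- trainable single-qubit rotations,

and the default circuit repeats it four times (12 trainable angles) and
closes with one final data re-encoding layer, so the state passes through
14 stages |x_1> = |00> ... |x_14> = |x>.

Conventions (fixed; they reproduce the closed-form amplitude recursions of
the method):

* amplitude order (|00>, |01>, |10>, |11>), qubit 1 in the left position;
* Rx(phi) = exp(-i phi/2 X) = cos(phi/2) I - i sin(phi/2) X;
* Ry(phi) = exp(-i phi/2 Y) = cos(phi/2) I - i sin(phi/2) Y;
* ZZ(theta) = exp(-i theta/2 Z(x)Z), i.e. phases e^{-i theta/2} on |00>,
  |11> and e^{+i theta/2} on |01>, |10>.

Every gate is unitary, so all operations preserve the state norm to
machine precision; pairwise overlaps |<x|x'>|^2 are invariant under global
phases and 4*pi-periodic in every angle (half-angle convention).

Besides the single-state operations, the module exposes a vectorized
:func:`embed_batch` which embeds many samples at once and can propagate
forward-mode tangents d|x>/d(x1), d|x>/d(x2), d|x>/d(theta_k) through the
circuit -- the machinery behind the analytic training gradient.
"""

from __future__ import annotations

import dataclasses

import numpy as np

_NORM_ATOL = 1e-9
#: sign pattern of Z(x)Z on the computational basis
_ZZ_SIGNS = np.array([1.0, -1.0, -1.0, 1.0])


@dataclasses.dataclass(frozen=True)
class EmbeddingConfig:
    """Shape of the circuit: number of ansatz layers and the closing encoder.

    ``params_per_layer`` is structurally 3 (one ZZ angle plus two Ry
    angles) and is exposed only for the parameter-count arithmetic.
    """

    n_layers: int = 4
    params_per_layer: int = 3
    final_encoding: bool = True

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError(f"n_layers must be positive, got {self.n_layers}")
        if self.params_per_layer != 3:
            raise ValueError("each ansatz layer has exactly 3 trainable angles (ZZ, Ry, Ry)")

    @property
    def n_quantum_params(self) -> int:
        return self.n_layers * self.params_per_layer

    @property
    def n_stages(self) -> int:
        """Number of circuit stages including the initial |00> state."""
        return 1 + 3 * self.n_layers + (1 if self.final_encoding else 0)


@dataclasses.dataclass
class QuantumParams:
    """The trainable circuit angles theta_1..theta_{3L}, in radians,
    consumed layer by layer as (ZZ, Ry, Ry)."""

    thetas: np.ndarray

    def __post_init__(self) -> None:
        self.thetas = np.atleast_1d(np.asarray(self.thetas, dtype=float))
        if self.thetas.ndim != 1:
            raise ValueError("thetas must be a flat vector of angles")

    def __len__(self) -> int:
        return self.thetas.shape[0]


@dataclasses.dataclass
class TwoQubitState:
    """Four complex amplitudes (alpha, beta, gamma, delta) with unit norm."""

    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=complex)
        if self.amplitudes.shape != (4,):
            raise ValueError("a two-qubit state has exactly 4 amplitudes")
        norm = np.linalg.norm(self.amplitudes)
        if abs(norm - 1.0) > _NORM_ATOL:
            raise ValueError(f"state is not normalized (norm {norm!r})")

    @classmethod
    def basis00(cls) -> "TwoQubitState":
        return cls(np.array([1.0, 0.0, 0.0, 0.0], dtype=complex))


def _rx(phi: float) -> np.ndarray:
    c, s = np.cos(phi / 2.0), np.sin(phi / 2.0)
    return np.array([[c, -1j * s], [-1j * s, c]])


def _ry(phi: float) -> np.ndarray:
    c, s = np.cos(phi / 2.0), np.sin(phi / 2.0)
    return np.array([[c, -s], [s, c]], dtype=complex)


def _drx(phi: float) -> np.ndarray:
    c, s = np.cos(phi / 2.0), np.sin(phi / 2.0)
    return 0.5 * np.array([[-s, -1j * c], [-1j * c, -s]])


def _dry(phi: float) -> np.ndarray:
    c, s = np.cos(phi / 2.0), np.sin(phi / 2.0)
    return 0.5 * np.array([[-s, -c], [c, -s]], dtype=complex)


def _zz_diag(theta: float) -> np.ndarray:
    return np.exp(-0.5j * theta * _ZZ_SIGNS)


def rx_pair(state: TwoQubitState, x1: float, x2: float) -> TwoQubitState:
    """Apply the data-encoding layer Rx(x1) (x) Rx(x2)."""
    return TwoQubitState(np.kron(_rx(x1), _rx(x2)) @ state.amplitudes)


def zz(state: TwoQubitState, theta: float) -> TwoQubitState:
    """Apply the ZZ(theta) entangler (parity-dependent phases)."""
    return TwoQubitState(_zz_diag(theta) * state.amplitudes)


def ry_pair(state: TwoQubitState, theta_a: float, theta_b: float) -> TwoQubitState:
    """Apply the trainable rotation layer Ry(theta_a) (x) Ry(theta_b)."""
    return TwoQubitState(np.kron(_ry(theta_a), _ry(theta_b)) @ state.amplitudes)


def embed(
    x1: float,
    x2: float,
    qparams: QuantumParams,
    config: EmbeddingConfig | None = None,
    return_trajectory: bool = False,
):
    """Embed the circuit inputs (x1, x2) starting from |00>.

    With the default configuration this applies 13 gate layers and, with
    ``return_trajectory=True``, returns the full list of 14 intermediate
    states |x_1>..|x_14>.
    """
    config = config or EmbeddingConfig()
    if len(qparams) != config.n_quantum_params:
        raise ValueError(
            f"expected {config.n_quantum_params} circuit angles "
            f"({config.n_layers} layers x 3), got {len(qparams)}"
        )
    state = TwoQubitState.basis00()
    trajectory = [state]
    th = qparams.thetas
    for layer in range(config.n_layers):
        state = rx_pair(state, x1, x2)
        trajectory.append(state)
        state = zz(state, th[3 * layer])
        trajectory.append(state)
        state = ry_pair(state, th[3 * layer + 1], th[3 * layer + 2])
        trajectory.append(state)
    if config.final_encoding:
        state = rx_pair(state, x1, x2)
        trajectory.append(state)
    return trajectory if return_trajectory else state


# ---------------------------------------------------------------------------
# batched embedding with optional forward-mode tangents


def _rx_batch(phi: np.ndarray, derivative: bool = False) -> np.ndarray:
    c, s = np.cos(phi / 2.0), np.sin(phi / 2.0)
    out = np.empty(phi.shape + (2, 2), dtype=complex)
    if derivative:
        out[..., 0, 0] = out[..., 1, 1] = -0.5 * s
        out[..., 0, 1] = out[..., 1, 0] = -0.5j * c
    else:
        out[..., 0, 0] = out[..., 1, 1] = c
        out[..., 0, 1] = out[..., 1, 0] = -1j * s
    return out


def _kron_batch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    return np.einsum("nij,nkl->nikjl", a, b).reshape(n, 4, 4)


def embed_batch(
    inputs: np.ndarray,
    thetas: np.ndarray,
    config: EmbeddingConfig | None = None,
    with_tangents: bool = False,
):
    """Embed N samples of circuit inputs at once.

    Parameters
    ----------
    inputs:
        (N, 2) array of (x1, x2) pairs.
    thetas:
        Flat vector of 3 * n_layers circuit angles.
    with_tangents:
        If true, also return a (N, 2 + T, 4) array of tangent vectors:
        slot 0 is d|x>/dx1, slot 1 is d|x>/dx2 and slot 2 + k is
        d|x>/d(theta_k).

    Returns
    -------
    states (N, 4) complex array, and with ``with_tangents`` also the
    tangent array.
    """
    config = config or EmbeddingConfig()
    inputs = np.asarray(inputs, dtype=float)
    thetas = np.asarray(thetas, dtype=float)
    if inputs.ndim != 2 or inputs.shape[1] != 2:
        raise ValueError("inputs must have shape (N, 2)")
    if thetas.shape != (config.n_quantum_params,):
        raise ValueError(
            f"expected {config.n_quantum_params} circuit angles, got {thetas.shape}"
        )
    n = inputs.shape[0]
    x1, x2 = inputs[:, 0], inputs[:, 1]
    psi = np.zeros((n, 4), dtype=complex)
    psi[:, 0] = 1.0
    tan = np.zeros((n, 2 + thetas.shape[0], 4), dtype=complex) if with_tangents else None

    # per-sample encoding matrices are reused by every layer
    u_enc = _kron_batch(_rx_batch(x1), _rx_batch(x2))
    if with_tangents:
        du1 = _kron_batch(_rx_batch(x1, derivative=True), _rx_batch(x2))
        du2 = _kron_batch(_rx_batch(x1), _rx_batch(x2, derivative=True))

    def apply_encoding():
        nonlocal psi, tan
        if tan is not None:
            new_tan = np.einsum("nij,ntj->nti", u_enc, tan)
            new_tan[:, 0] += np.einsum("nij,nj->ni", du1, psi)
            new_tan[:, 1] += np.einsum("nij,nj->ni", du2, psi)
            tan = new_tan
        psi = np.einsum("nij,nj->ni", u_enc, psi)

    def apply_zz(theta: float, slot: int):
        nonlocal psi, tan
        diag = _zz_diag(theta)
        if tan is not None:
            tan = tan * diag
            tan[:, slot] += psi * (-0.5j * _ZZ_SIGNS * diag)
        psi = psi * diag

    def apply_ry(theta_a: float, theta_b: float, slot_a: int, slot_b: int):
        nonlocal psi, tan
        u = np.kron(_ry(theta_a), _ry(theta_b))
        if tan is not None:
            dua = np.kron(_dry(theta_a), _ry(theta_b))
            dub = np.kron(_ry(theta_a), _dry(theta_b))
            tan = tan @ u.T
            tan[:, slot_a] += psi @ dua.T
            tan[:, slot_b] += psi @ dub.T
        psi = psi @ u.T

    for layer in range(config.n_layers):
        apply_encoding()
        apply_zz(thetas[3 * layer], 2 + 3 * layer)
        apply_ry(thetas[3 * layer + 1], thetas[3 * layer + 2],
                 2 + 3 * layer + 1, 2 + 3 * layer + 2)
    if config.final_encoding:
        apply_encoding()

    return (psi, tan) if with_tangents else psi
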