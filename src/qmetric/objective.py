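"""Class-ensemble density matrices, Hilbert-Schmidt distance and the cost.

Training separates the two embedded class ensembles by maximizing the
Hilbert-Schmidt distance

    D_hs(rho, sigma) = tr[(rho - sigma)^2]  in [0, 2],

between the class density matrices rho = (1/Ma) sum_a |a><a| and
sigma = (1/Mb) sum_b |b><b|, or equivalently by minimizing the cost

    C = 1 - D_hs / 2  in [0, 1],

which is 0 for orthogonal pure ensembles and 1 for identical ensembles.
Expanding the trace gives the pairwise-overlap form

    D_hs = mean_aa' |<a|a'>|^2 + mean_bb' |<b|b'>|^2 - 2 mean_ab |<a|b>|^2,

which is what the training loop evaluates (no complex 4x4 algebra in the
differentiated path); the trace form is retained for reported values and
as an independent route in the tests.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np

from .circuit import TwoQubitState

_HERMITIAN_ATOL = 1e-8


def _as_state_array(states) -> np.ndarray:
    """Accept an (N, 4) array, a ClassEnsemble or a sequence of states."""
    if isinstance(states, ClassEnsemble):
        states = states.states
    if isinstance(states, np.ndarray) and states.ndim == 2:
        arr = np.asarray(states, dtype=complex)
    else:
        arr = np.array(
            [s.amplitudes if isinstance(s, TwoQubitState) else np.asarray(s, dtype=complex)
             for s in states]
        )
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise ValueError("expected a collection of 4-amplitude states")
    if arr.shape[0] == 0:
        raise ValueError("ensemble is empty")
    return arr


@dataclasses.dataclass
class ClassEnsemble:
    """Embedded training states of one class."""

    states: np.ndarray  # (M, 4) complex amplitudes
    label: object = None

    def __post_init__(self) -> None:
        self.states = _as_state_array(self.states)
        norms = np.linalg.norm(self.states, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("ensemble contains non-normalized states")

    def __len__(self) -> int:
        return self.states.shape[0]


@dataclasses.dataclass
class DensityMatrix:
    """4x4 Hermitian, PSD, trace-1 ensemble average of |x><x|."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=complex)
        if self.matrix.shape != (4, 4):
            raise ValueError("density matrix must be 4x4")
        if not np.allclose(self.matrix, self.matrix.conj().T, atol=_HERMITIAN_ATOL):
            raise ValueError("density matrix is not Hermitian")
        if abs(np.trace(self.matrix).real - 1.0) > 1e-8:
            raise ValueError(f"density matrix trace is {np.trace(self.matrix)!r}, expected 1")
        if np.linalg.eigvalsh(self.matrix).min() < -1e-8:
            raise ValueError("density matrix has a negative eigenvalue")

    @property
    def purity(self) -> float:
        return float(np.real(np.trace(self.matrix @ self.matrix)))


def density_matrix(ensemble: ClassEnsemble | Iterable | np.ndarray) -> DensityMatrix:
    """Equal-weight average of the outer products |x><x|."""
    arr = _as_state_array(ensemble)
    mat = np.einsum("ni,nj->ij", arr, arr.conj()) / arr.shape[0]
    return DensityMatrix(mat)


def hs_distance(rho: DensityMatrix, sigma: DensityMatrix) -> float:
    """tr[(rho - sigma)^2], symmetric, in [0, 2] for trace-1 arguments."""
    diff = rho.matrix - sigma.matrix
    return float(np.real(np.trace(diff @ diff)))


def cost(rho: DensityMatrix, sigma: DensityMatrix) -> float:
    """C = 1 - D_hs / 2, the quantity minimized during training."""
    return 1.0 - 0.5 * hs_distance(rho, sigma)


def overlap(x: TwoQubitState, x_prime: TwoQubitState) -> float:
    """Fidelity |<x|x'>|^2 between two embedded states."""
    return float(np.abs(np.vdot(x.amplitudes, x_prime.amplitudes)) ** 2)


def overlap_matrix(states: np.ndarray, other: np.ndarray | None = None) -> np.ndarray:
    """All pairwise overlaps |<x_i|y_j>|^2 between two state collections."""
    a = _as_state_array(states)
    b = a if other is None else _as_state_array(other)
    return np.abs(a.conj() @ b.T) ** 2


def cost_from_gram_blocks(k_aa: np.ndarray, k_bb: np.ndarray, k_ab: np.ndarray) -> float:
    """Cost from precomputed overlap blocks (within-A, within-B, cross)."""
    d = np.mean(k_aa) + np.mean(k_bb) - 2.0 * np.mean(k_ab)
    return 1.0 - 0.5 * float(d)


def cost_from_states(
    states_a: np.ndarray | ClassEnsemble | Sequence,
    states_b: np.ndarray | ClassEnsemble | Sequence,
) -> float:
    """Cost via the pairwise-overlap expansion (the training-loop route)."""
    a = _as_state_array(states_a)
    b = _as_state_array(states_b)
    return cost_from_gram_blocks(
        overlap_matrix(a), overlap_matrix(b), overlap_matrix(a, b)
    )
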