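"""The hybrid model: a 2 x n linear layer feeding the two-qubit circuit.

An n-feature sample is multiplied by a trainable 2 x n matrix (no bias)
to give the two circuit inputs (x1, x2), which the quantum feature map
embeds into a two-qubit state.  With the default 4-layer circuit the
model therefore carries 2n + 12 trainable parameters in total.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np

from .circuit import EmbeddingConfig, QuantumParams, TwoQubitState, embed


@dataclasses.dataclass
class LinearProjection:
    """The trainable 2 x n front-end matrix."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != 2 or self.weights.shape[1] < 1:
            raise ValueError(f"weights must have shape (2, n>=1), got {self.weights.shape}")

    @property
    def n_features(self) -> int:
        return self.weights.shape[1]


@dataclasses.dataclass
class HybridParams:
    """All trainable parameters: linear weights plus circuit angles."""

    linear: LinearProjection
    quantum: QuantumParams

    @property
    def n_params(self) -> int:
        return self.linear.weights.size + len(self.quantum)


def project(features: np.ndarray, linear: LinearProjection) -> tuple[float, float]:
    """(x1, x2) = W . features."""
    features = np.asarray(features, dtype=float)
    if features.shape != (linear.n_features,):
        raise ValueError(
            f"feature vector of length {features.shape} does not match "
            f"2x{linear.n_features} projection"
        )
    x1, x2 = linear.weights @ features
    return float(x1), float(x2)


def param_count(n_features: int, config: EmbeddingConfig | None = None) -> int:
    """Total trainable parameters, 2 * n_features + 3 * n_layers."""
    if n_features < 1:
        raise ValueError(f"n_features must be at least 1, got {n_features}")
    config = config or EmbeddingConfig()
    return 2 * n_features + config.n_quantum_params


def flattened_feature_count(shape: Sequence[int]) -> int:
    """Feature count of a flattened raw input, e.g. an H x W x C image."""
    if not shape or any(int(s) < 1 for s in shape):
        raise ValueError(f"shape entries must be positive, got {shape}")
    return math.prod(int(s) for s in shape)


def _init_normal_uniform(rng: np.random.Generator, n_features: int, n_quantum: int):
    weights = rng.normal(0.0, 0.1, size=(2, n_features))
    thetas = rng.uniform(0.0, 2.0 * np.pi, size=n_quantum)
    return weights, thetas


INIT_SCHEMES = {"normal-uniform": _init_normal_uniform}


def init_params(
    n_features: int,
    seed: int,
    scheme: str = "normal-uniform",
    config: EmbeddingConfig | None = None,
) -> HybridParams:
    """Random initialization, deterministic per seed.

    The default scheme draws linear weights from N(0, 0.1^2) and circuit
    angles uniformly on [0, 2*pi).
    """
    if n_features < 1:
        raise ValueError(f"n_features must be at least 1, got {n_features}")
    if scheme not in INIT_SCHEMES:
        raise ValueError(
            f"unknown init scheme {scheme!r}; available: {sorted(INIT_SCHEMES)}"
        )
    config = config or EmbeddingConfig()
    rng = np.random.default_rng(seed)
    weights, thetas = INIT_SCHEMES[scheme](rng, n_features, config.n_quantum_params)
    return HybridParams(LinearProjection(weights), QuantumParams(thetas))


def embed_sample(
    features: np.ndarray,
    params: HybridParams,
    config: EmbeddingConfig | None = None,
) -> TwoQubitState:
    """Full embedding of one sample: linear projection then circuit."""
    x1, x2 = project(features, params.linear)
    return embed(x1, x2, params.quantum, config)


# --- flat-vector view used by the optimizer -------------------------------

def flatten_params(params: HybridParams) -> np.ndarray:
    """Concatenate [linear weights row-major, circuit angles]."""
    return np.concatenate([params.linear.weights.ravel(), params.quantum.thetas])


def unflatten_params(vector: np.ndarray, n_features: int,
                     config: EmbeddingConfig | None = None) -> HybridParams:
    config = config or EmbeddingConfig()
    vector = np.asarray(vector, dtype=float)
    expected = 2 * n_features + config.n_quantum_params
    if vector.shape != (expected,):
        raise ValueError(f"expected a parameter vector of length {expected}, got {vector.shape}")
    weights = vector[: 2 * n_features].reshape(2, n_features)
    thetas = vector[2 * n_features:]
    return HybridParams(LinearProjection(weights.copy()), QuantumParams(thetas.copy()))


def params_to_json(params: HybridParams, path: str | Path) -> None:
    doc = {
        "weights": params.linear.weights.tolist(),
        "thetas": params.quantum.thetas.tolist(),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def params_from_json(path: str | Path) -> HybridParams:
    doc = json.loads(Path(path).read_text())
    return HybridParams(
        LinearProjection(np.array(doc["weights"], dtype=float)),
        QuantumParams(np.array(doc["thetas"], dtype=float)),
    )
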