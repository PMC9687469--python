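"""Gradient training of all 2n + 12 parameters with RMSProp.

The protocol follows the study conditions: 1500 optimization steps, a
batch of 10 samples drawn per class per step, RMSProp with step size
0.01 (decay 0.9, epsilon 1e-8).  Each step evaluates the Hilbert-Schmidt
cost on the two class mini-batches and updates the flattened parameter
vector [linear weights row-major, circuit angles].

Gradients are analytic: forward-mode tangents of each embedded state with
respect to (x1, x2) and the circuit angles are propagated through the
circuit, combined through the pairwise-overlap expansion of the cost, and
chained onto the linear weights via dx_s/dW[s, j] = feature_j.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .circuit import EmbeddingConfig, embed_batch
from .model import HybridParams, flatten_params, unflatten_params
from .table import LabeledTable

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol; the defaults are the study's (1500, 10, 0.01)."""

    steps: int = 1500
    batch_size: int = 10
    step_size: float = 0.01
    rms_decay: float = 0.9
    rms_epsilon: float = 1e-8
    seed: int = 0
    batch_mode: str = "per-class"  # or "pooled"

    def __post_init__(self) -> None:
        if self.steps < 0:
            raise ValueError("steps must be non-negative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if not 0.0 < self.rms_decay < 1.0:
            raise ValueError("rms_decay must lie in (0, 1)")
        if self.rms_epsilon <= 0:
            raise ValueError("rms_epsilon must be positive")
        if self.batch_mode not in ("per-class", "pooled"):
            raise ValueError(f"unknown batch_mode {self.batch_mode!r}")


@dataclasses.dataclass
class OptimizerState:
    """RMSProp accumulator: running average of squared gradients."""

    sq_grad_avg: np.ndarray
    step_index: int = 0

    def __post_init__(self) -> None:
        self.sq_grad_avg = np.asarray(self.sq_grad_avg, dtype=float)
        if (self.sq_grad_avg < 0).any():
            raise ValueError("squared-gradient average must be non-negative")


@dataclasses.dataclass
class TrainTrace:
    """Batch cost after 0..steps updates (length steps + 1)."""

    costs: np.ndarray
    batch_indices: list | None = None


def cost_and_gradient(
    params: HybridParams,
    batch_a: np.ndarray,
    batch_b: np.ndarray,
    config: EmbeddingConfig | None = None,
) -> tuple[float, np.ndarray]:
    """Batch cost and its gradient w.r.t. the flattened parameter vector.

    ``batch_a`` / ``batch_b`` are (M, n) feature matrices of the two
    classes (at least one row each).
    """
    config = config or EmbeddingConfig()
    batch_a = np.atleast_2d(np.asarray(batch_a, dtype=float))
    batch_b = np.atleast_2d(np.asarray(batch_b, dtype=float))
    if batch_a.shape[0] == 0 or batch_b.shape[0] == 0:
        raise ValueError("both class batches must be non-empty")
    w = params.linear.weights
    th = params.quantum.thetas
    ma, mb = batch_a.shape[0], batch_b.shape[0]

    a, ta = embed_batch(batch_a @ w.T, th, config, with_tangents=True)
    b, tb = embed_batch(batch_b @ w.T, th, config, with_tangents=True)

    z_aa = a.conj() @ a.T
    z_bb = b.conj() @ b.T
    z_ab = a.conj() @ b.T
    d_hs = (
        (np.abs(z_aa) ** 2).mean()
        + (np.abs(z_bb) ** 2).mean()
        - 2.0 * (np.abs(z_ab) ** 2).mean()
    )
    c = 1.0 - 0.5 * d_hs

    # inner products of tangents with states: e_xy[s, m, n] = <dX_m^(s)|Y_n>
    e_aa = np.einsum("msd,nd->smn", ta.conj(), a)
    e_bb = np.einsum("msd,nd->smn", tb.conj(), b)
    e_ab = np.einsum("msd,nd->smn", ta.conj(), b)
    e_ba = np.einsum("msd,nd->smn", tb.conj(), a)

    # per-sample derivatives of D_hs w.r.t. the circuit inputs (slots 0, 1)
    gxa = (4.0 / ma**2) * np.real(
        np.einsum("mn,smn->ms", z_aa.conj(), e_aa[:2])
    ) - (4.0 / (ma * mb)) * np.real(np.einsum("mn,smn->ms", z_ab.conj(), e_ab[:2]))
    gxb = (4.0 / mb**2) * np.real(
        np.einsum("mn,smn->ms", z_bb.conj(), e_bb[:2])
    ) - (4.0 / (ma * mb)) * np.real(np.einsum("am,sma->ms", z_ab, e_ba[:2]))

    # shared circuit-angle derivatives of D_hs
    ds_aa = 4.0 * np.real(np.einsum("mn,smn->s", z_aa.conj(), e_aa[2:]))
    ds_bb = 4.0 * np.real(np.einsum("mn,smn->s", z_bb.conj(), e_bb[2:]))
    ds_ab = 2.0 * np.real(
        np.einsum("mn,smn->s", z_ab.conj(), e_ab[2:])
        + np.einsum("mn,snm->s", z_ab, e_ba[2:])
    )
    d_theta = ds_aa / ma**2 + ds_bb / mb**2 - 2.0 * ds_ab / (ma * mb)

    # chain rule: C = 1 - D/2, x = W f
    dxa = -0.5 * gxa  # (Ma, 2) = dC/d(x1, x2) per class-A sample
    dxb = -0.5 * gxb
    dw = dxa.T @ batch_a + dxb.T @ batch_b
    dth = -0.5 * d_theta
    return float(c), np.concatenate([dw.ravel(), dth])


def gradient(
    params: HybridParams,
    batch_a: np.ndarray,
    batch_b: np.ndarray,
    config: EmbeddingConfig | None = None,
) -> np.ndarray:
    """Gradient of the batch cost (see :func:`cost_and_gradient`)."""
    return cost_and_gradient(params, batch_a, batch_b, config)[1]


def rmsprop_step(
    params: np.ndarray,
    grads: np.ndarray,
    state: OptimizerState,
    config: TrainConfig,
) -> tuple[np.ndarray, OptimizerState]:
    """One RMSProp update on a flat parameter vector."""
    params = np.asarray(params, dtype=float)
    grads = np.asarray(grads, dtype=float)
    if params.shape != grads.shape or params.shape != state.sq_grad_avg.shape:
        raise ValueError("parameter, gradient and accumulator lengths differ")
    avg = config.rms_decay * state.sq_grad_avg + (1.0 - config.rms_decay) * grads**2
    new_params = params - config.step_size * grads / np.sqrt(avg + config.rms_epsilon)
    return new_params, OptimizerState(avg, state.step_index + 1)


def _draw_batch(rng: np.random.Generator, n: int, size: int) -> np.ndarray:
    # with replacement only when the class is smaller than the batch
    return rng.choice(n, size=size, replace=n < size)


def train(
    train_table: LabeledTable,
    init: HybridParams,
    config: TrainConfig | None = None,
    embed_config: EmbeddingConfig | None = None,
    record_batches: bool = False,
) -> tuple[HybridParams, TrainTrace]:
    """Run the full optimization; deterministic per ``config.seed``.

    Per step, ``batch_size`` samples are drawn from each class (the
    ``pooled`` batch mode instead draws ``batch_size`` rows overall and
    splits them by label, redrawing until both classes are present).
    Returns the final parameters and the batch-cost trace.
    """
    config = config or TrainConfig()
    embed_config = embed_config or EmbeddingConfig()
    classes = train_table.classes
    if len(classes) != 2:
        raise ValueError(f"training needs exactly 2 classes, found {len(classes)}")
    feats_a = train_table.class_features(classes[0])
    feats_b = train_table.class_features(classes[1])
    if init.linear.n_features != train_table.n_features:
        raise ValueError(
            f"params expect {init.linear.n_features} features, table has {train_table.n_features}"
        )

    rng = np.random.default_rng(config.seed)
    vec = flatten_params(init)
    opt = OptimizerState(np.zeros_like(vec))
    costs = np.empty(config.steps + 1)
    batches: list | None = [] if record_batches else None

    def sample_batches():
        if config.batch_mode == "per-class":
            ia = _draw_batch(rng, feats_a.shape[0], config.batch_size)
            ib = _draw_batch(rng, feats_b.shape[0], config.batch_size)
            return ia, ib
        n_total = train_table.n_samples
        while True:
            rows = rng.choice(n_total, size=config.batch_size,
                              replace=n_total < config.batch_size)
            lab = train_table.labels[rows]
            if (lab == classes[0]).any() and (lab == classes[1]).any():
                break
        a_pos = np.flatnonzero(train_table.labels == classes[0])
        b_pos = np.flatnonzero(train_table.labels == classes[1])
        ia = np.searchsorted(a_pos, rows[lab == classes[0]])
        ib = np.searchsorted(b_pos, rows[lab == classes[1]])
        return ia, ib

    for step in range(config.steps):
        ia, ib = sample_batches()
        if batches is not None:
            batches.append((ia, ib))
        params = unflatten_params(vec, train_table.n_features, embed_config)
        c, g = cost_and_gradient(params, feats_a[ia], feats_b[ib], embed_config)
        costs[step] = c
        vec, opt = rmsprop_step(vec, g, opt, config)
        if step % 100 == 0:
            logger.debug("step %d: batch cost %.4f", step, c)

    # closing entry: cost of a fresh batch at the final parameters
    ia, ib = sample_batches()
    params = unflatten_params(vec, train_table.n_features, embed_config)
    costs[config.steps], _ = cost_and_gradient(params, feats_a[ia], feats_b[ib], embed_config)
    return params, TrainTrace(costs, batches)
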