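"""Two-class synthetic feature tables with controllable geometry.

The generator emulates the structure of clinical tabular data such as the
Breast Cancer Wisconsin (Diagnostic) table: two partially overlapping
classes, a few hundred samples and correlated continuous features.  The
class-conditional model is Gaussian with a shared covariance

    Sigma = (cov_scale^2 / cov_rank) * W W^T + noise_sd^2 * I,

where ``W`` (n_features x cov_rank, standard-normal entries drawn once per
seed) supplies a low-rank correlated component for PCA to find, and the two
class means sit at +/- separation/2 along a random unit direction, so their
Euclidean distance is exactly ``separation``.  The 1/cov_rank scaling keeps
the per-feature variance of the shared component at cov_scale^2 regardless
of rank.

Two named regimes bundle the study conditions used throughout the test
suite and examples: an overparameterized regime (features >> training
samples, strongly overlapping classes) and a well-conditioned regime
(training samples >> parameters, separable classes).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.model_selection import train_test_split

from .table import LabeledTable

#: internal class labels; negative class first, matching the sign classifier
CLASS_LABELS = (-1, 1)


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the two-class Gaussian generator.

    Parameters
    ----------
    n_per_class:
        Samples drawn per class; the table has ``2 * n_per_class`` rows.
    n_features:
        Number of feature columns.
    separation:
        Euclidean distance between the two class mean vectors, in units of
        the (standardized) feature scale.  ``0`` makes the classes
        identically distributed.
    cov_rank:
        Rank of the shared low-rank covariance component; ``0`` leaves pure
        isotropic noise.
    noise_sd:
        Standard deviation of the isotropic noise added to every feature.
    cov_scale:
        Per-feature standard deviation contributed by the low-rank
        component (``1.0`` by default; ``0.0`` disables it).
    seed:
        Seed for all randomness; identical spec => bit-identical table.
    """

    n_per_class: int = 285
    n_features: int = 30
    separation: float = 3.0
    cov_rank: int = 5
    noise_sd: float = 1.0
    cov_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError(f"n_per_class must be positive, got {self.n_per_class}")
        if self.n_features < 1:
            raise ValueError(f"n_features must be positive, got {self.n_features}")
        if self.separation < 0:
            raise ValueError(f"separation must be non-negative, got {self.separation}")
        if not 0 <= self.cov_rank <= self.n_features:
            raise ValueError(
                f"cov_rank must lie in [0, n_features={self.n_features}], got {self.cov_rank}"
            )
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be positive, got {self.noise_sd}")
        if self.cov_scale < 0:
            raise ValueError(f"cov_scale must be non-negative, got {self.cov_scale}")


def generate_two_class_table(spec: SyntheticSpec) -> LabeledTable:
    """Draw a labeled table from the class-conditional Gaussian model."""
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_per_class, spec.n_features

    direction = rng.normal(size=p)
    direction /= np.linalg.norm(direction)
    offset = 0.5 * spec.separation * direction

    if spec.cov_rank > 0:
        mixing = rng.normal(size=(p, spec.cov_rank)) * (spec.cov_scale / np.sqrt(spec.cov_rank))
    else:
        mixing = np.zeros((p, 0))

    rows = []
    for sign in (-1.0, +1.0):
        latent = rng.normal(size=(n, spec.cov_rank))
        noise = rng.normal(scale=spec.noise_sd, size=(n, p))
        rows.append(sign * offset + latent @ mixing.T + noise)
    features = np.vstack(rows)
    labels = np.repeat(CLASS_LABELS, n)
    return LabeledTable(features, labels)


def split_train_test(
    table: LabeledTable,
    train_fraction: float,
    seed: int,
    stratify: bool = True,
) -> tuple[LabeledTable, LabeledTable]:
    """Deterministic row partition into train and test tables.

    The split is stratified by default so both classes keep their
    proportions within one sample even in small test sets; pass
    ``stratify=False`` for a simple random partition.  Train and test are
    disjoint and their union restores the input rows.
    """
    if not 0 < train_fraction < 1:
        raise ValueError(f"train_fraction must lie in (0, 1), got {train_fraction}")
    if stratify:
        _, counts = np.unique(table.labels, return_counts=True)
        if counts.min() < 2:
            raise ValueError("cannot stratify: a class has fewer than 2 samples")
    idx = np.arange(table.n_samples)
    train_idx, test_idx = train_test_split(
        idx,
        train_size=train_fraction,
        random_state=seed,
        shuffle=True,
        stratify=table.labels if stratify else None,
    )
    return table.subset(np.sort(train_idx)), table.subset(np.sort(test_idx))


def overparameterized_spec(seed: int = 0) -> SyntheticSpec:
    """Study conditions where trainable parameters vastly outnumber samples.

    200 features (2*200 + 12 = 412 parameters) against a few dozen
    training rows, with classes separated by far less than the noise scale
    so that the population distributions overlap almost completely --
    emulating a feature-rich, sample-poor image-feature table.
    """
    return SyntheticSpec(
        n_per_class=50, n_features=200, separation=1.0, cov_rank=10,
        noise_sd=1.0, seed=seed,
    )


def well_conditioned_spec(seed: int = 0) -> SyntheticSpec:
    """Study conditions with many more training samples than parameters.

    10 features (32 parameters) against several hundred rows with a clear
    but overlapping class separation -- emulating a clinical table where a
    low-capacity model generalizes.
    """
    return SyntheticSpec(
        n_per_class=334, n_features=10, separation=3.0, cov_rank=3,
        noise_sd=1.0, seed=seed,
    )
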