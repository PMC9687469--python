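"""Per-feature standardization and PCA, fitted on training data only.

Both transforms follow the usual leakage-safe protocol: parameters are
estimated from the training split and then applied unchanged to held-out
rows.  Standardization uses the population (1/N) standard deviation,
matching the semantics of the standard scaler used on the clinical data;
constant columns are flagged and passed through with sd treated as 1.
PCA is computed as an eigendecomposition of the training sample
covariance (1/(N-1)), which makes the loadings/explained-variance
contract direct; each loading column is sign-fixed so its
largest-magnitude entry is non-negative, making results independent of
the eigensolver.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np

from .table import LabeledTable

_CONSTANT_TOL = 1e-12


@dataclasses.dataclass
class StandardizationParams:
    means: np.ndarray
    sds: np.ndarray
    constant: np.ndarray  # boolean mask of constant columns (sd forced to 1)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.constant = np.asarray(self.constant, dtype=bool)
        if not self.means.shape == self.sds.shape == self.constant.shape:
            raise ValueError("means, sds and constant mask must have equal length")
        if (self.sds <= 0).any():
            raise ValueError("standard deviations must be positive")

    @property
    def n_features(self) -> int:
        return self.means.shape[0]


@dataclasses.dataclass
class PCAParams:
    loadings: np.ndarray            # (n_features, k), orthonormal columns
    explained_variance: np.ndarray  # (k,), non-increasing
    k: int
    center: np.ndarray              # (n_features,) training column means

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        if self.loadings.ndim != 2 or self.loadings.shape[1] != self.k:
            raise ValueError("loadings must be an (n_features x k) matrix")
        if self.explained_variance.shape != (self.k,):
            raise ValueError("explained_variance must have length k")
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(self.k), atol=1e-8):
            raise ValueError("loading columns are not orthonormal")
        if np.any(np.diff(self.explained_variance) > 1e-10):
            raise ValueError("explained_variance must be non-increasing")

    @property
    def n_features(self) -> int:
        return self.loadings.shape[0]


def fit_standardizer(train: LabeledTable) -> StandardizationParams:
    """Per-column mean and population sd of the training features."""
    if train.n_samples < 2:
        raise ValueError("need at least 2 rows to fit a standardizer")
    means = train.features.mean(axis=0)
    sds = train.features.std(axis=0, ddof=0)
    constant = sds <= _CONSTANT_TOL
    if constant.any():
        names = [train.feature_names[i] for i in np.flatnonzero(constant)]
        warnings.warn(f"constant feature column(s) {names}: sd treated as 1", stacklevel=2)
    sds = np.where(constant, 1.0, sds)
    return StandardizationParams(means, sds, constant)


def apply_standardizer(table: LabeledTable, params: StandardizationParams) -> LabeledTable:
    """Transform each column as (x - mean) / sd; labels untouched."""
    if table.n_features != params.n_features:
        raise ValueError(
            f"table has {table.n_features} features but params were fitted on {params.n_features}"
        )
    scaled = (table.features - params.means) / params.sds
    return table.with_features(scaled, table.feature_names)


def fit_pca(train: LabeledTable, k: int) -> PCAParams:
    """Top-k eigenpairs of the training covariance matrix.

    ``k`` must lie in [1, min(n_samples - 1, n_features)].
    """
    n, p = train.n_samples, train.n_features
    k_max = min(n - 1, p)
    if not 1 <= k <= k_max:
        raise ValueError(f"k must lie in [1, {k_max}] for a {n}x{p} table, got {k}")
    center = train.features.mean(axis=0)
    centered = train.features - center
    cov = centered.T @ centered / (n - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1][:k]
    loadings = eigvec[:, order]
    explained = np.clip(eigval[order], 0.0, None)
    # deterministic sign: largest-magnitude entry of each column non-negative
    flip = loadings[np.abs(loadings).argmax(axis=0), np.arange(k)] < 0
    loadings[:, flip] *= -1.0
    return PCAParams(loadings, explained, k, center)


def project_pca(table: LabeledTable, params: PCAParams) -> LabeledTable:
    """Project (centered) features onto the principal axes; columns PC1..PCk."""
    if table.n_features != params.n_features:
        raise ValueError(
            f"table has {table.n_features} features but PCA was fitted on {params.n_features}"
        )
    scores = (table.features - params.center) @ params.loadings
    names = [f"PC{i + 1}" for i in range(params.k)]
    return table.with_features(scores, names)


def params_to_json(
    path: str | Path,
    standardizer: StandardizationParams | None = None,
    pca: PCAParams | None = None,
) -> None:
    """Serialize fitted preprocessing parameters for reuse across runs."""
    doc: dict = {}
    if standardizer is not None:
        doc["standardizer"] = {
            "means": standardizer.means.tolist(),
            "sds": standardizer.sds.tolist(),
            "constant": standardizer.constant.tolist(),
        }
    if pca is not None:
        doc["pca"] = {
            "loadings": pca.loadings.tolist(),
            "explained_variance": pca.explained_variance.tolist(),
            "k": pca.k,
            "center": pca.center.tolist(),
        }
    Path(path).write_text(json.dumps(doc, indent=1))


def params_from_json(path: str | Path) -> tuple[StandardizationParams | None, PCAParams | None]:
    doc = json.loads(Path(path).read_text())
    standardizer = pca = None
    if "standardizer" in doc:
        s = doc["standardizer"]
        standardizer = StandardizationParams(
            np.array(s["means"]), np.array(s["sds"]), np.array(s["constant"])
        )
    if "pca" in doc:
        p = doc["pca"]
        pca = PCAParams(
            np.array(p["loadings"]), np.array(p["explained_variance"]), int(p["k"]),
            np.array(p["center"]),
        )
    return standardizer, pca
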