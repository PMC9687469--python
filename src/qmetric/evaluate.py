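"""Fidelity-kernel classification and the evaluation outputs.

A trained embedding is turned into a classifier by comparing a test
state's mean fidelity with each class's embedded training ensemble:

    f(x) = (1/Ma) sum_a |<a|x>|^2 - (1/Mb) sum_b |<b|x>|^2
         = <x| rho - sigma |x>,

and predicting class A when f(x) > 0, class B when f(x) < 0 (ties go to
the configured tie label, class B by default).  This is the
nearest-neighbour form of a quantum kernel classifier with uniform
weights 1/Ma, 1/Mb.

Evaluation of one train/test split produces the tabulated quantities:
full-split training and test costs, plus precision, recall and F1 of the
test predictions for a configurable positive class (default: the
lexicographically second label).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from sklearn.metrics import precision_score, recall_score, f1_score

from .circuit import EmbeddingConfig, TwoQubitState, embed_batch
from .model import HybridParams
from .objective import cost_from_states, overlap_matrix, _as_state_array
from .table import LabeledTable


@dataclasses.dataclass
class MetricsRecord:
    """One row of the result tables."""

    n_features_used: int
    used_pca: bool
    training_cost: float
    test_cost: float
    precision: float
    recall: float
    f1: float


@dataclasses.dataclass
class FidelityClassifier:
    """Embedded training ensembles plus the parameters that produced them."""

    states_a: np.ndarray
    states_b: np.ndarray
    label_a: object
    label_b: object
    params: HybridParams
    config: EmbeddingConfig = dataclasses.field(default_factory=EmbeddingConfig)
    tie_label: object = None  # defaults to label_b (the negative class)

    def __post_init__(self) -> None:
        self.states_a = _as_state_array(self.states_a)
        self.states_b = _as_state_array(self.states_b)
        if self.tie_label is None:
            self.tie_label = self.label_b

    @classmethod
    def from_table(
        cls,
        train: LabeledTable,
        params: HybridParams,
        config: EmbeddingConfig | None = None,
        tie_label: object = None,
    ) -> "FidelityClassifier":
        """Embed every training sample once; classes in sorted label order."""
        config = config or EmbeddingConfig()
        classes = train.classes
        if len(classes) != 2:
            raise ValueError(f"need exactly 2 classes, found {len(classes)}")
        inputs = train.features @ params.linear.weights.T
        states = embed_batch(inputs, params.quantum.thetas, config)
        mask_a = train.labels == classes[0]
        return cls(states[mask_a], states[~mask_a], classes[0], classes[1],
                   params, config, tie_label)

    def embed_features(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=float))
        return embed_batch(features @ self.params.linear.weights.T,
                           self.params.quantum.thetas, self.config)


def decision_values(features: np.ndarray, clf: FidelityClassifier) -> np.ndarray:
    """f(x) for each row of ``features``."""
    x = clf.embed_features(features)
    k_a = overlap_matrix(clf.states_a, x)
    k_b = overlap_matrix(clf.states_b, x)
    return k_a.mean(axis=0) - k_b.mean(axis=0)


def decision_value(x, clf: FidelityClassifier) -> float:
    """f(x) for a single feature vector or pre-embedded state."""
    if isinstance(x, TwoQubitState):
        state = x.amplitudes[None, :]
        k_a = overlap_matrix(clf.states_a, state)
        k_b = overlap_matrix(clf.states_b, state)
        return float(k_a.mean(axis=0)[0] - k_b.mean(axis=0)[0])
    return float(decision_values(np.atleast_2d(x), clf)[0])


def predict(features: np.ndarray, clf: FidelityClassifier) -> np.ndarray:
    """sgn(f(x)) mapped to class labels; f = 0 resolves to the tie label."""
    f = decision_values(features, clf)
    out = np.where(f > 0, clf.label_a, clf.label_b)
    out = np.where(f == 0, clf.tie_label, out)
    return out


def compute_metrics(predictions: np.ndarray, truth: np.ndarray, positive_label) -> dict:
    """Precision, recall and F1 for the given positive class.

    A zero denominator (no predicted or no true positives) yields 0 with
    a warning rather than an error.
    """
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape:
        raise ValueError("predictions and truth have different lengths")
    if predictions.size == 0:
        raise ValueError("cannot score an empty prediction vector")
    if not (predictions == positive_label).any():
        warnings.warn("no positive predictions: precision reported as 0", stacklevel=2)
    if not (truth == positive_label).any():
        warnings.warn("no positive truth labels: recall reported as 0", stacklevel=2)
    kw = dict(pos_label=positive_label, zero_division=0, labels=np.unique(np.concatenate([truth, predictions])))
    return {
        "precision": float(precision_score(truth, predictions, **kw)),
        "recall": float(recall_score(truth, predictions, **kw)),
        "f1": float(f1_score(truth, predictions, **kw)),
    }


def gram_matrix(states) -> np.ndarray:
    """Symmetric matrix of pairwise overlaps |<x|x'>|^2, unit diagonal."""
    return overlap_matrix(_as_state_array(states))


def xy_coordinates(table: LabeledTable, params: HybridParams) -> np.ndarray:
    """The (x1, x2) circuit inputs of every row (for scatter exports)."""
    return table.features @ params.linear.weights.T


def evaluate_split(
    train: LabeledTable,
    test: LabeledTable,
    params: HybridParams,
    config: EmbeddingConfig | None = None,
    positive_label=None,
    tie_label=None,
    used_pca: bool = False,
) -> MetricsRecord:
    """Assemble one result row for a trained model.

    Training and test costs are computed from the full-split class
    ensembles; classification of the test rows uses the training
    ensembles as the kernel reference set.
    """
    config = config or EmbeddingConfig()
    clf = FidelityClassifier.from_table(train, params, config, tie_label)
    if positive_label is None:
        positive_label = clf.label_b  # lexicographically second class

    test_states = clf.embed_features(test.features)
    mask_a = test.labels == clf.label_a
    if not mask_a.any() or mask_a.all():
        raise ValueError("test split must contain both classes")
    training_cost = cost_from_states(clf.states_a, clf.states_b)
    test_cost = cost_from_states(test_states[mask_a], test_states[~mask_a])

    k_a = overlap_matrix(clf.states_a, test_states)
    k_b = overlap_matrix(clf.states_b, test_states)
    f = k_a.mean(axis=0) - k_b.mean(axis=0)
    preds = np.where(f > 0, clf.label_a, clf.label_b)
    preds = np.where(f == 0, clf.tie_label, preds)
    scores = compute_metrics(preds, test.labels, positive_label)
    return MetricsRecord(
        n_features_used=train.n_features,
        used_pca=used_pca,
        training_cost=training_cost,
        test_cost=test_cost,
        **scores,
    )
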