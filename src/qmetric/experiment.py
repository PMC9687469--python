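"""End-to-end experiment runner and the PCA sweep driver.

One sweep reproduces a result table: the input table is split 3:2 into
train and test, standardized (fit on the training split), and a model is
trained and evaluated once per feature-reduction setting -- the no-PCA
baseline first, then each requested number of principal components.
Every random choice is controlled by an explicit seed (split_seed,
init_seed, the trainer's batch seed), and all toggles are written to a
run-metadata JSON so a run is fully reconstructible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .circuit import EmbeddingConfig
from .evaluate import (FidelityClassifier, MetricsRecord, evaluate_split,
                       gram_matrix, xy_coordinates)
from .model import init_params
from .preprocess import apply_standardizer, fit_pca, fit_standardizer, project_pca
from .synthetic import SyntheticSpec, generate_two_class_table, split_train_test
from .table import LabeledTable
from .train import TrainConfig, train

logger = logging.getLogger(__name__)

METRICS_COLUMNS = [
    "No. of Features", "Training Cost", "Test Cost", "Precision", "Recall", "F1-Score",
]


def load_table(path, label_column: str = "label") -> LabeledTable:
    """Load a labeled CSV table (see :meth:`LabeledTable.from_csv`)."""
    return LabeledTable.from_csv(path, label_column)


def breast_cancer_table() -> LabeledTable:
    """The UCI ML Breast Cancer Wisconsin (Diagnostic) table.

    569 samples x 30 quantitative cell-nucleus features, labels
    'benign' / 'malignant', as packaged with scikit-learn.
    """
    from sklearn.datasets import load_breast_cancer

    data = load_breast_cancer()
    labels = np.asarray(data.target_names)[data.target]
    return LabeledTable(data.data, labels, list(data.feature_names))


@dataclasses.dataclass
class ExperimentConfig:
    """Everything needed to reproduce one sweep."""

    table: LabeledTable | None = None
    input_path: str | None = None
    synthetic: SyntheticSpec | None = None
    pca_components: Sequence[int] = ()
    include_baseline: bool = True
    train_fraction: float = 0.6
    split_seed: int = 0
    init_seed: int = 0
    init_scheme: str = "normal-uniform"
    stratify: bool = True
    fit_on_all: bool = False
    train_config: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    embed_config: EmbeddingConfig = dataclasses.field(default_factory=EmbeddingConfig)
    positive_label: object = None
    tie_label: object = None
    output_dir: str | Path | None = None

    def resolve_table(self) -> LabeledTable:
        sources = [s is not None for s in (self.table, self.input_path, self.synthetic)]
        if sum(sources) != 1:
            raise ValueError("provide exactly one of table, input_path or synthetic")
        if self.table is not None:
            return self.table
        if self.input_path is not None:
            return load_table(self.input_path)
        return generate_two_class_table(self.synthetic)


def _metadata(config: ExperimentConfig, table: LabeledTable) -> dict:
    return {
        "qmetric_version": _version,
        "n_samples": table.n_samples,
        "n_features": table.n_features,
        "classes": [str(c) for c in table.classes],
        "pca_components": list(config.pca_components),
        "include_baseline": config.include_baseline,
        "train_fraction": config.train_fraction,
        "split_seed": config.split_seed,
        "init_seed": config.init_seed,
        "init_scheme": config.init_scheme,
        "stratify": config.stratify,
        "fit_on_all": config.fit_on_all,
        "train_config": dataclasses.asdict(config.train_config),
        "embed_config": dataclasses.asdict(config.embed_config),
        "positive_label": None if config.positive_label is None else str(config.positive_label),
        "tie_label": None if config.tie_label is None else str(config.tie_label),
        "synthetic": None if config.synthetic is None else dataclasses.asdict(config.synthetic),
        "input_path": config.input_path,
    }


def metrics_dataframe(records: Sequence[MetricsRecord]) -> pd.DataFrame:
    """Result rows in the tabulated column order, 4 decimal places."""
    rows = [
        {
            "No. of Features": r.n_features_used,
            "Training Cost": f"{r.training_cost:.4f}",
            "Test Cost": f"{r.test_cost:.4f}",
            "Precision": f"{r.precision:.4f}",
            "Recall": f"{r.recall:.4f}",
            "F1-Score": f"{r.f1:.4f}",
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)


def _export_row_outputs(out: Path, train_t, test_t, params, config, trace) -> None:
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"step": np.arange(len(trace.costs)), "batch_cost": trace.costs}).to_csv(
        out / "trace.csv", index=False
    )
    for split_name, split in (("train", train_t), ("test", test_t)):
        clf = FidelityClassifier.from_table(split, params, config.embed_config) \
            if len(split.classes) == 2 else None
        if clf is None:
            continue
        states = np.vstack([clf.states_a, clf.states_b])
        gram = gram_matrix(states)
        pd.DataFrame(gram).to_csv(out / f"gram_{split_name}.csv", index=False, header=False)
    xy_rows = []
    for split_name, split in (("train", train_t), ("test", test_t)):
        xy = xy_coordinates(split, params)
        for i in range(split.n_samples):
            xy_rows.append(
                {"sample": i, "x1": xy[i, 0], "x2": xy[i, 1],
                 "label": split.labels[i], "split": split_name}
            )
    pd.DataFrame(xy_rows).to_csv(out / "scatter.csv", index=False)


def run_sweep(config: ExperimentConfig) -> list[MetricsRecord]:
    """Split, preprocess, train and evaluate once per feature setting."""
    table = config.resolve_table()
    for k in config.pca_components:
        if not 1 <= k <= table.n_features:
            raise ValueError(
                f"pca_components entry {k} outside [1, n_features={table.n_features}]"
            )

    train_t, test_t = split_train_test(
        table, config.train_fraction, config.split_seed, stratify=config.stratify
    )
    scaler = fit_standardizer(table if config.fit_on_all else train_t)
    train_std = apply_standardizer(train_t, scaler)
    test_std = apply_standardizer(test_t, scaler)

    entries: list[int | None] = ([None] if config.include_baseline else [])
    entries += list(config.pca_components)

    out_dir = Path(config.output_dir) if config.output_dir is not None else None
    records: list[MetricsRecord] = []
    for entry in entries:
        try:
            if entry is None:
                tr, te, used_pca = train_std, test_std, False
            else:
                pca = fit_pca(train_std if not config.fit_on_all
                              else apply_standardizer(table, scaler), entry)
                tr = project_pca(train_std, pca)
                te = project_pca(test_std, pca)
                used_pca = True
            params0 = init_params(tr.n_features, config.init_seed,
                                  config.init_scheme, config.embed_config)
            params, trace = train(tr, params0, config.train_config, config.embed_config)
            record = evaluate_split(
                tr, te, params, config.embed_config,
                positive_label=config.positive_label,
                tie_label=config.tie_label,
                used_pca=used_pca,
            )
            records.append(record)
            logger.info(
                "sweep entry %s: train cost %.4f, test cost %.4f, F1 %.4f",
                "baseline" if entry is None else f"{entry} PCs",
                record.training_cost, record.test_cost, record.f1,
            )
            if out_dir is not None:
                name = "baseline" if entry is None else f"pc_{entry}"
                _export_row_outputs(out_dir / name, tr, te, params, config, trace)
        except Exception as exc:
            label = "baseline" if entry is None else f"{entry} principal components"
            raise RuntimeError(f"sweep entry '{label}' failed: {exc}") from exc

    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        metrics_dataframe(records).to_csv(out_dir / "metrics.csv", index=False)
        (out_dir / "run_meta.json").write_text(
            json.dumps(_metadata(config, table), indent=1, sort_keys=True)
        )
    return records
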