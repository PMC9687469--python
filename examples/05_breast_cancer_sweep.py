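"""PCA sweep on the breast-cancer diagnostic table (one split seed).

Reproduces one result-table row set: the 30 standardized features are
reduced to 30/16/8/4/2 principal components (plus a no-PCA baseline),
and a model is trained and scored per setting.  Takes a couple of
minutes (six 1500-step trainings).
"""

import qmetric as qm

config = qm.ExperimentConfig(
    table=qm.breast_cancer_table(),
    pca_components=[30, 16, 8, 4, 2],
    split_seed=0,
    init_seed=0,
    train_config=qm.TrainConfig(seed=0),
    positive_label="malignant",
)
records = qm.run_sweep(config)
print(qm.metrics_dataframe(records).to_string(index=False))
# Row 1 is the no-PCA baseline (60 linear parameters); the remaining rows
# use PCA.  Mid-range component counts (8-16) tend to balance expressivity
# against overfitting; very few components cost F1 and raise the test cost.
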