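"""Contrast the overparameterized and well-conditioned training regimes.

With far more parameters than training samples the embedding memorizes
the training set (training cost near 0) while test samples stay
unseparated (test cost near 1).  With far more samples than parameters
the train and test costs track each other.
"""

import qmetric as qm


def run(spec, train_fraction, seed=0):
    table = qm.generate_two_class_table(spec)
    train_t, test_t = qm.split_train_test(table, train_fraction, seed)
    params0 = qm.init_params(train_t.n_features, seed)
    params, _ = qm.train(train_t, params0, qm.TrainConfig(seed=seed))
    rec = qm.evaluate_split(train_t, test_t, params)
    n_params = qm.param_count(train_t.n_features)
    print(f"  {train_t.n_samples} train samples, {n_params} parameters: "
          f"train cost {rec.training_cost:.4f}, test cost {rec.test_cost:.4f}, "
          f"F1 {rec.f1:.4f}")


print("overparameterized regime (200 features, overlapping classes):")
run(qm.overparameterized_spec(seed=0), train_fraction=0.4)

print("well-conditioned regime (10 features, separated classes):")
run(qm.well_conditioned_spec(seed=0), train_fraction=0.6)
# The first line shows severe overfitting (tiny train cost, test cost
# near its maximum of 1); the second generalizes (similar costs).
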