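import numpy as np
import pytest

import qmetric as qm
from qmetric import FidelityClassifier, TwoQubitState
from qmetric.evaluate import decision_value, decision_values


def _basis(i):
    v = np.zeros(4, dtype=complex)
    v[i] = 1.0
    return v


def _clf(states_a, states_b, label_a="a", label_b="b", **kw):
    params = qm.init_params(2, seed=0)
    return FidelityClassifier(states_a, states_b, label_a, label_b, params, **kw)


class TestDecisionValue:
    def test_matching_class_a_and_orthogonal_class_b_gives_one(self):
        clf = _clf(_basis(0)[None, :], _basis(1)[None, :])
        assert decision_value(TwoQubitState(_basis(0)), clf) == pytest.approx(1.0)

    def test_identical_ensembles_give_zero_everywhere(self, random_states):
        states = random_states(4, seed=0)
        clf = _clf(states, states.copy())
        for probe in random_states(6, seed=1):
            assert decision_value(TwoQubitState(probe), clf) == pytest.approx(0.0, abs=1e-12)

    def test_kernel_sum_equals_density_matrix_form(self, random_states):
        a = random_states(5, seed=2)
        b = random_states(3, seed=3)
        m = qm.density_matrix(a).matrix - qm.density_matrix(b).matrix
        clf = _clf(a, b)
        for probe in random_states(8, seed=4):
            want = float(np.real(probe.conj() @ m @ probe))
            got = decision_value(TwoQubitState(probe), clf)
            assert got == pytest.approx(want, abs=1e-10)

    def test_swapping_ensembles_negates_decision(self, random_states):
        a = random_states(4, seed=5)
        b = random_states(4, seed=6)
        probes = random_states(5, seed=7)
        fwd = [decision_value(TwoQubitState(p), _clf(a, b)) for p in probes]
        rev = [decision_value(TwoQubitState(p), _clf(b, a)) for p in probes]
        assert np.allclose(fwd, -np.asarray(rev), atol=1e-12)

    def test_bounded_by_one_and_continuous_under_duplication(self, random_states):
        a = random_states(3, seed=8)
        b = random_states(3, seed=9)
        probe = TwoQubitState(random_states(1, seed=10)[0])
        f0 = decision_value(probe, _clf(a, b))
        assert abs(f0) <= 1.0
        # duplicating an existing class-A state keeps f bounded and close
        f1 = decision_value(probe, _clf(np.vstack([a, a[:1]]), b))
        assert abs(f1) <= 1.0
        assert abs(f1 - f0) < 0.5


class TestPredict:
    def test_sign_maps_to_class_labels(self):
        # zero weights and angles embed every sample at |00>: f > 0 against
        # the |00> class-A ensemble, f < 0 if the ensembles are swapped
        a, b = _basis(0)[None, :], _basis(1)[None, :]
        params = qm.HybridParams(qm.LinearProjection(np.zeros((2, 1))),
                                 qm.QuantumParams(np.zeros(12)))
        feats = np.zeros((1, 1))
        assert qm.predict(feats, FidelityClassifier(a, b, "ant", "bee", params))[0] == "ant"
        assert qm.predict(feats, FidelityClassifier(b, a, "ant", "bee", params))[0] == "bee"

    def test_tie_resolves_to_configured_label(self, random_states):
        # mirror-image ensembles: any probe overlapping both equally ties
        states = random_states(2, seed=11)
        params = qm.HybridParams(
            qm.LinearProjection(np.zeros((2, 1))), qm.QuantumParams(np.zeros(12))
        )
        clf = FidelityClassifier(states, states.copy(), "a", "b", params)
        assert qm.predict(np.zeros((1, 1)), clf)[0] == "b"  # default: negative class
        clf_a = FidelityClassifier(states, states.copy(), "a", "b", params, tie_label="a")
        assert qm.predict(np.zeros((1, 1)), clf_a)[0] == "a"

    def test_vectorized_decisions_match_scalar(self, random_states, rng):
        params = qm.init_params(3, seed=1)
        table = qm.generate_two_class_table(
            qm.SyntheticSpec(n_per_class=6, n_features=3, cov_rank=1, seed=2)
        )
        clf = FidelityClassifier.from_table(table, params)
        feats = rng.normal(size=(4, 3))
        vals = decision_values(feats, clf)
        for i in range(4):
            assert vals[i] == pytest.approx(decision_value(feats[i], clf), abs=1e-12)


class TestMetrics:
    def test_all_correct(self):
        m = qm.compute_metrics(["x", "y", "x"], ["x", "y", "x"], positive_label="x")
        assert m == {"precision": 1.0, "recall": 1.0, "f1": 1.0}

    def test_hand_computed_confusion_table(self):
        # TP=2, FP=1, FN=1 -> P = R = F1 = 2/3
        truth = np.array([1, 1, 1, 0, 0, 0])
        preds = np.array([1, 1, 0, 1, 0, 0])
        m = qm.compute_metrics(preds, truth, positive_label=1)
        assert m["precision"] == pytest.approx(2 / 3)
        assert m["recall"] == pytest.approx(2 / 3)
        assert m["f1"] == pytest.approx(2 / 3)

    def test_no_positive_predictions_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="no positive predictions"):
            m = qm.compute_metrics([0, 0], [1, 0], positive_label=1)
        assert m["precision"] == 0.0 and m["recall"] == 0.0

    def test_f1_is_harmonic_mean(self, rng):
        truth = rng.integers(0, 2, size=50)
        preds = rng.integers(0, 2, size=50)
        m = qm.compute_metrics(preds, truth, positive_label=1)
        if m["precision"] > 0 and m["recall"] > 0:
            want = 2 * m["precision"] * m["recall"] / (m["precision"] + m["recall"])
            assert m["f1"] == pytest.approx(want, abs=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            qm.compute_metrics([0], [0, 1], positive_label=1)


class TestGram:
    def test_single_and_orthogonal(self):
        assert np.allclose(qm.gram_matrix(_basis(0)[None, :]), [[1.0]])
        pair = np.vstack([_basis(0), _basis(1)])
        assert np.allclose(qm.gram_matrix(pair), np.eye(2))

    def test_symmetric_unit_diagonal(self, random_states):
        g = qm.gram_matrix(random_states(3, seed=12))
        assert np.allclose(g, g.T, atol=1e-12)
        assert np.allclose(np.diag(g), 1.0, atol=1e-12)
        assert np.all((g >= 0) & (g <= 1 + 1e-12))

    def test_trained_toy_shows_block_structure(self, trained_toy):
        train_t, _, params, _ = trained_toy
        clf = FidelityClassifier.from_table(train_t, params)
        within_a = qm.gram_matrix(clf.states_a)
        within_b = qm.gram_matrix(clf.states_b)
        cross = qm.overlap_matrix(clf.states_a, clf.states_b)
        assert within_a.mean() > cross.mean()
        assert within_b.mean() > cross.mean()


class TestEvaluateSplit:
    def test_train_equals_test_on_trained_toy(self, trained_toy):
        train_t, _, params, _ = trained_toy
        rec = qm.evaluate_split(train_t, train_t, params)
        assert rec.training_cost == pytest.approx(rec.test_cost)
        assert rec.precision > 0.95 and rec.recall > 0.95 and rec.f1 > 0.95

    def test_chance_level_on_zero_separation(self):
        f1s = []
        for seed in range(3):
            table = qm.generate_two_class_table(
                qm.SyntheticSpec(n_per_class=120, n_features=6, separation=0.0,
                                 cov_rank=2, seed=seed)
            )
            tr, te = qm.split_train_test(table, 0.6, seed)
            params = qm.init_params(6, seed=seed + 10)  # untrained random model
            f1s.append(qm.evaluate_split(tr, te, params).f1)
        assert abs(np.median(f1s) - 0.5) < 0.15

    def test_record_fields_and_xy_export(self, trained_toy):
        train_t, test_t, params, _ = trained_toy
        rec = qm.evaluate_split(train_t, test_t, params, used_pca=False)
        assert rec.n_features_used == train_t.n_features
        assert 0 <= rec.training_cost <= 1 and 0 <= rec.test_cost <= 1
        xy = qm.xy_coordinates(test_t, params)
        assert xy.shape == (test_t.n_samples, 2)
        assert np.allclose(xy, test_t.features @ params.linear.weights.T)
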