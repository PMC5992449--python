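import math

import numpy as np
import pytest
import sympy
from scipy.stats import rankdata

from rpistack.ensemble import (
    ConfusionCounts,
    EnsembleModel,
    assemble_predict,
    confusion,
    fold_assignments,
    metrics,
    roc_auc,
    stack,
    train_level0,
)


def pairwise_auc(scores, y):
    """O(n^2) Mann-Whitney oracle with half-credit for ties."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_scores(self):
        y = np.array([1, 0, 1, 0])
        c = confusion(y.astype(float), y)
        assert (c.TP, c.TN, c.FP, c.FN) == (2, 2, 0, 0)

    def test_all_zero_scores_predict_negative(self):
        c = confusion(np.zeros(6), [1, 1, 0, 0, 0, 1])
        assert c.TP == 0 and c.FP == 0 and c.FN == 3 and c.TN == 3

    def test_matches_explicit_loop(self, rng):
        scores = rng.random(50)
        y = rng.integers(0, 2, size=50)
        c = confusion(scores, y, threshold=0.4)
        TP = TN = FP = FN = 0
        for s, t in zip(scores, y):
            pred = s >= 0.4
            if pred and t == 1:
                TP += 1
            elif pred and t == 0:
                FP += 1
            elif not pred and t == 1:
                FN += 1
            else:
                TN += 1
        assert (c.TP, c.TN, c.FP, c.FN) == (TP, TN, FP, FN)

    def test_nonfinite_scores_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.array([0.5, np.nan]), [0, 1])


class TestMetrics:
    def test_perfect_classifier(self):
        m = metrics(ConfusionCounts(TP=50, TN=50, FP=0, FN=0))
        assert all(m[k] == 1.0 for k in ("acc", "sen", "spec", "prec", "mcc"))

    def test_perfectly_wrong_classifier(self):
        m = metrics(ConfusionCounts(TP=0, TN=0, FP=50, FN=50))
        assert m["acc"] == 0.0 and m["mcc"] == -1.0

    def test_hand_evaluated_mixed_table(self):
        m = metrics(ConfusionCounts(TP=40, FN=10, TN=35, FP=15))
        assert m["acc"] == pytest.approx(0.75)
        assert m["sen"] == pytest.approx(0.8)
        assert m["spec"] == pytest.approx(0.7)
        assert m["prec"] == pytest.approx(8 / 11)
        expected_mcc = (40 * 35 - 15 * 10) / math.sqrt(55 * 50 * 50 * 45)
        assert m["mcc"] == pytest.approx(expected_mcc, abs=1e-12)

    def test_zero_denominator_rates_flagged(self):
        with pytest.warns(UserWarning, match="sensitivity"):
            m = metrics(ConfusionCounts(TP=0, TN=5, FP=0, FN=0))
        assert math.isnan(m["sen"]) and m["mcc"] == 0.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(0, 0, 0, 0))

    def test_agrees_with_symbolic_formulas_on_random_tables(self, rng):
        TP, TN, FP, FN = sympy.symbols("TP TN FP FN", positive=True)
        exprs = {
            "acc": (TN + TP) / (TN + TP + FN + FP),
            "sen": TP / (TP + FN),
            "spec": TN / (TN + FP),
            "prec": TP / (TP + FP),
            "mcc": (TP * TN - FP * FN)
            / sympy.sqrt((TP + FP) * (TP + FN) * (TN + FP) * (TN + FN)),
        }
        for _ in range(1000):
            tp, tn, fp, fn = (int(v) for v in rng.integers(1, 200, size=4))
            m = metrics(ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn))
            subs = {TP: tp, TN: tn, FP: fp, FN: fn}
            for key, expr in exprs.items():
                assert m[key] == pytest.approx(
                    float(expr.evalf(subs=subs)), abs=1e-10
                ), key


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _, _ = roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), [1, 1, 0, 0])
        assert auc == 1.0

    def test_uninformative_scores(self):
        auc, _, _ = roc_auc(np.full(10, 0.5), [1, 0] * 5)
        assert auc == pytest.approx(0.5)

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(10):
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=20)
            y = rng.integers(0, 2, size=20)
            if len(set(y.tolist())) < 2:
                continue
            auc, _, _ = roc_auc(scores, y)
            assert auc == pytest.approx(pairwise_auc(scores, y), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.9]), [1, 1])


class TestAssembling:
    def test_zero_weight_stacked_model_outputs_half(self):
        model = EnsembleModel(w=np.zeros(4), strategy="stacked")
        scores = assemble_predict(model, np.array([[0.1, 0.9, 0.4]]))
        assert scores[0] == 0.5

    def test_average_strategy(self):
        model = EnsembleModel(strategy="average")
        assert assemble_predict(model, np.array([[0.2, 0.4, 0.9]]))[0] == pytest.approx(0.5)

    def test_majority_strategy(self):
        model = EnsembleModel(strategy="majority")
        assert assemble_predict(model, np.array([[0.6, 0.7, 0.2]]))[0] == pytest.approx(2 / 3)

    def test_probabilities_outside_unit_interval_rejected(self):
        model = EnsembleModel(strategy="average")
        with pytest.raises(ValueError):
            assemble_predict(model, np.array([[1.2, 0.4, 0.5]]))

    def test_equal_weight_stacking_degenerates_to_averaging(self, rng):
        """With equal level-0 weights the stacked score is a strictly monotone
        transform of the column average, so rankings and ROC/AUC coincide."""
        P = rng.random((80, 3))
        y = rng.integers(0, 2, size=80)
        stacked = assemble_predict(
            EnsembleModel(w=np.array([2.0, 2.0, 2.0, -3.0]), strategy="stacked"), P
        )
        averaged = assemble_predict(EnsembleModel(strategy="average"), P)
        np.testing.assert_array_equal(rankdata(stacked), rankdata(averaged))
        assert roc_auc(stacked, y)[0] == roc_auc(averaged, y)[0]

    def test_stack_on_identical_separating_columns_reaches_auc_one(self):
        y = np.array([0] * 20 + [1] * 20)
        col = np.where(y == 1, 0.9, 0.1)
        P = np.column_stack([col, col, col])
        model = stack(P, y)
        assert roc_auc(assemble_predict(model, P), y)[0] == 1.0

    def test_stack_weights_favor_the_informative_column(self, rng):
        y = rng.integers(0, 2, size=400)
        informative = np.clip(0.6 * y + 0.2 + 0.1 * rng.normal(size=400), 0, 1)
        P = np.column_stack([informative, rng.random(400), rng.random(400)])
        model = stack(P, y)
        weights = np.abs(model.w[:-1])
        assert np.argmax(weights) == 0


class TestLevel0:
    def _signal_features(self, rng, n=200):
        y = rng.integers(0, 2, size=n)
        feats = {
            name: y[:, None] + 0.5 * rng.normal(size=(n, 8))
            for name in ("SA-RF", "SA-FT-RF", "RPISeq-RF")
        }
        return feats, y

    def test_training_auc_beats_chance_on_planted_signal(self, rng):
        feats, y = self._signal_features(rng)
        predictors = train_level0(feats, y, n_trees=50, seed=0)
        assert len(predictors) == 3
        for p in predictors:
            auc, _, _ = roc_auc(p.predict_proba1(feats[p.name]), y)
            assert auc > 0.5

    def test_deterministic_per_seed(self, rng):
        feats, y = self._signal_features(rng)
        a = train_level0(feats, y, n_trees=30, seed=5)
        b = train_level0(feats, y, n_trees=30, seed=5)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(
                pa.predict_proba1(feats[pa.name]), pb.predict_proba1(feats[pb.name])
            )

    def test_row_count_mismatch_names_the_source(self, rng):
        feats, y = self._signal_features(rng)
        feats["RPISeq-RF"] = feats["RPISeq-RF"][:-1]
        with pytest.raises(ValueError, match="RPISeq-RF"):
            train_level0(feats, y)

    def test_single_class_rejected(self, rng):
        feats, y = self._signal_features(rng)
        with pytest.raises(ValueError):
            train_level0(feats, np.zeros_like(y))


def test_fold_assignments_partition_the_data():
    y = np.array([0, 1] * 26)
    folds = fold_assignments(y, n_folds=5, seed=0)
    all_test = np.concatenate([te for _, te in folds])
    assert sorted(all_test.tolist()) == list(range(len(y)))
    sizes = [len(te) for _, te in folds]
    assert max(sizes) - min(sizes) <= 1
    for tr, te in folds:
        assert set(tr) & set(te) == set()
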