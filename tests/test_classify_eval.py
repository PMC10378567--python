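import itertools

import numpy as np
import pytest

from fusioncad import (
    adaboost_predict,
    adaboost_train,
    classifier_adapters,
    evaluate,
    train_and_evaluate,
    wilcoxon_rank_sum,
)
from fusioncad.classify_eval import CLASSIFIER_NAMES, AdaBoostModel
from helpers import best_single_stump_accuracy, exact_rank_sum_p, hand_metrics


class TestAdaBoost:
    def test_separable_data_one_round_is_perfect(self):
        x = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        y = np.array([-1, -1, -1, 1, 1, 1])
        model = adaboost_train(x, y, T=5)
        assert model.n_rounds == 1  # eps_1 = 0 stops training
        assert np.isfinite(model.alphas[0]) and model.alphas[0] > 5
        assert (adaboost_predict(model, x) == y).all()

    def test_weights_stay_normalized_each_round(self, rng):
        # re-derive the weight recurrence alongside training and check Z_t
        x = rng.standard_normal((60, 3))
        y = np.where(x[:, 0] + 0.5 * rng.standard_normal(60) > 0, 1, -1)
        model = adaboost_train(x, y, T=8)
        n = len(y)
        d = np.full(n, 1.0 / n)
        for alpha, h in zip(model.alphas, model.weak_learners):
            pred = h.predict(x)
            d = d * np.exp(-alpha * y * pred)
            d = d / d.sum()
            assert d.sum() == pytest.approx(1.0, abs=1e-12)

    def test_boosting_beats_every_single_stump_on_xor(self):
        rng = np.random.default_rng(0)  # seed verified by direct simulation
        x = rng.integers(0, 2, (200, 2)).astype(float)
        y = np.where((x[:, 0].astype(int) ^ x[:, 1].astype(int)) > 0, 1, -1)
        x = x + rng.normal(0, 0.05, x.shape)
        model = adaboost_train(x, y, T=10)
        acc = float((adaboost_predict(model, x) == y).mean())
        assert acc > best_single_stump_accuracy(x, y)

    def test_training_error_non_increasing_on_separable_data(self, rng):
        x = rng.standard_normal((80, 2))
        y = np.where(x[:, 0] + x[:, 1] > 0, 1, -1)
        errs = []
        for t in (1, 3, 6, 12):
            model = adaboost_train(x, y, T=t)
            errs.append(float((adaboost_predict(model, x) != y).mean()))
        assert all(b <= a + 1e-12 for a, b in zip(errs, errs[1:]))

    def test_predict_matches_weighted_vote_oracle(self, rng):
        x = rng.standard_normal((40, 2))
        y = np.where(x[:, 0] > 0.2, 1, -1)
        model = adaboost_train(x, y, T=6)
        xt = rng.standard_normal((20, 2))
        score = np.zeros(20)
        for alpha, h in zip(model.alphas, model.weak_learners):
            score += alpha * h.predict(xt)
        oracle = np.where(score >= 0, 1, -1)
        assert (adaboost_predict(model, xt) == oracle).all()

    def test_negating_alphas_flips_every_non_tied_prediction(self, rng):
        x = rng.standard_normal((50, 2))
        y = np.where(x[:, 1] > 0, 1, -1)
        model = adaboost_train(x, y, T=5)
        xt = rng.standard_normal((30, 2))
        base = adaboost_predict(model, xt)
        flipped_model = AdaBoostModel(
            weak_learners=model.weak_learners,
            alphas=[-a for a in model.alphas],
            T=model.T,
        )
        flipped = adaboost_predict(flipped_model, xt)
        score = np.zeros(30)
        for alpha, h in zip(model.alphas, model.weak_learners):
            score += alpha * h.predict(xt)
        non_tied = score != 0
        assert (flipped[non_tied] == -base[non_tied]).all()

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError):
            adaboost_train(np.zeros((4, 1)), np.ones(4), T=2)


class TestEvaluate:
    def test_perfect_prediction_gives_unit_iba(self):
        y = np.array([1, 1, 0, 0])
        rep = evaluate(y, y)
        assert rep.accuracy == 1.0
        assert rep.iba == 1.0  # (1 + 0.1*0) * (1*1)

    def test_table_row_iba_reproduces_printed_92_percent(self):
        # recall 0.96, specificity 0.96 at alpha 0.1 -> IBA 0.9216 -> 92%
        y_true = np.array([1] * 50 + [0] * 50)
        y_pred = y_true.copy()
        y_pred[:2] = 0
        y_pred[50:52] = 1
        rep = evaluate(y_true, y_pred)
        assert rep.recall == pytest.approx(0.96)
        assert rep.specificity == pytest.approx(0.96)
        assert round(100 * rep.iba) == 92

    def test_all_cells_one_gives_half_everywhere(self):
        rep = evaluate(np.array([1, 1, 0, 0]), np.array([1, 0, 1, 0]))
        assert rep.accuracy == 0.5
        assert rep.precision == 0.5
        assert rep.recall == 0.5
        assert rep.f1 == 0.5

    def test_matches_hand_formulas_on_small_confusions(self):
        import warnings

        for tp, tn, fp, fn in itertools.product(range(3), repeat=4):
            if tp + tn + fp + fn == 0:
                continue
            y_true = np.array([1] * (tp + fn) + [0] * (tn + fp))
            y_pred = np.array([1] * tp + [0] * fn + [0] * tn + [1] * fp)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = evaluate(y_true, y_pred)
            expect = hand_metrics(tp, tn, fp, fn)
            got = {
                "accuracy": rep.accuracy, "recall": rep.recall,
                "specificity": rep.specificity, "precision": rep.precision,
                "f1": rep.f1, "dominance": rep.dominance, "iba": rep.iba,
            }
            for key, val in expect.items():
                if np.isnan(val):
                    assert np.isnan(got[key]), (key, tp, tn, fp, fn)
                else:
                    assert got[key] == pytest.approx(val), (key, tp, tn, fp, fn)

    def test_undefined_metric_warns_and_reports_nan(self):
        with pytest.warns(UserWarning, match="undefined"):
            rep = evaluate(np.array([0, 0]), np.array([0, 0]))
        assert np.isnan(rep.recall)

    def test_iba_reduces_to_recall_times_specificity_when_balanced(self):
        # dominance = 0 whenever recall == specificity
        y_true = np.array([1] * 10 + [0] * 10)
        y_pred = y_true.copy()
        y_pred[0] = 0
        y_pred[10] = 1
        rep = evaluate(y_true, y_pred)
        assert rep.dominance == pytest.approx(0.0)
        assert rep.iba == pytest.approx(rep.recall * rep.specificity)

    def test_macro_average_is_mean_of_class_views(self):
        y_true = np.array([1] * 8 + [0] * 4)
        y_pred = np.array([1] * 6 + [0] * 2 + [0] * 3 + [1])
        rep = evaluate(y_true, y_pred)
        for key in ("recall", "precision", "f1"):
            expected = np.mean(
                [rep.per_class["malignant"][key], rep.per_class["benign"][key]]
            )
            assert rep.macro[key] == pytest.approx(expected)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.array([]), np.array([]))


class TestWilcoxon:
    def test_extreme_separation_small_groups(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.w == 6  # minimum possible rank sum
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.1)  # 2/20 assignments as extreme
        assert not res.reject

    def test_identical_samples_fail_to_reject(self):
        res = wilcoxon_rank_sum([5.0, 5.0, 7.0], [5.0, 5.0, 7.0])
        assert res.p_value > 0.5
        assert not res.reject

    def test_agrees_with_exhaustive_enumeration_small_sizes(self, rng):
        for na in (2, 3, 5):
            for nb in (2, 4, 5):
                a = rng.standard_normal(na)
                b = rng.standard_normal(nb) + 0.8
                res = wilcoxon_rank_sum(a, b)
                w_ref, p_ref = exact_rank_sum_p(a, b)
                assert res.w == pytest.approx(w_ref)
                assert res.p_value == pytest.approx(p_ref)

    def test_agrees_with_scipy_at_large_samples(self, rng):
        from scipy.stats import ranksums

        a = rng.standard_normal(60)
        b = rng.standard_normal(70) + 0.4
        res = wilcoxon_rank_sum(a, b)
        ref = ranksums(a, b)
        assert res.method == "normal"
        assert res.p_value == pytest.approx(ref.pvalue, abs=0.01)

    def test_null_rejection_rate_near_five_percent(self):
        rng = np.random.default_rng(2024)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = rng.standard_normal(50)
            b = rng.standard_normal(50)
            if wilcoxon_rank_sum(a, b).reject:
                rejections += 1
        # binomial(1000, 0.05) three-sigma band
        assert abs(rejections / n_rep - 0.05) < 0.021

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestAdapters:
    def test_all_adapters_learn_the_planted_signal(self, planted_table):
        idx = np.arange(planted_table.n_samples)
        train = planted_table.subset_rows(idx[:300])
        test = planted_table.subset_rows(idx[300:])
        for name in CLASSIFIER_NAMES:
            rep = train_and_evaluate(train, test, classifier=name, seed=0)
            assert rep.accuracy >= 0.9, name

    def test_prediction_shape_and_determinism(self, planted_table):
        x, y = planted_table.x(), planted_table.y()
        for name in CLASSIFIER_NAMES:
            p1 = classifier_adapters(name, seed=1).fit(x, y).predict(x[:25])
            p2 = classifier_adapters(name, seed=1).fit(x, y).predict(x[:25])
            assert len(p1) == 25
            assert (np.asarray(p1) == np.asarray(p2)).all(), name

    def test_unknown_name_lists_valid_choices(self):
        with pytest.raises(ValueError, match="xgboost"):
            classifier_adapters("svm")
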