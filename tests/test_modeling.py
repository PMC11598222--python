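"""Fold plans, undersampling, metrics, training, tuning and external CV."""

import numpy as np
import pytest

import skinsens as ss
from skinsens.modeling import ConfusionCounts, default_hyperparameters, _inner_cv_ccr


def brute_force_binary_metrics(y, calls):
    """Direct counting oracle for SE/SP/CCR/PPV/NPV."""
    tp = sum(1 for a, b in zip(y, calls) if a == 1 and b == 1)
    tn = sum(1 for a, b in zip(y, calls) if a == 0 and b == 0)
    fp = sum(1 for a, b in zip(y, calls) if a == 0 and b == 1)
    fn = sum(1 for a, b in zip(y, calls) if a == 1 and b == 0)
    div = lambda a, b: a / b if b else None
    se, sp = div(tp, tp + fn), div(tn, tn + fp)
    ccr = (se + sp) / 2 if se is not None and sp is not None else None
    return se, sp, ccr, div(tp, tp + fp), div(tn, tn + fn)


class TestFoldPlan:
    def test_partition_sizes(self):
        plan = ss.make_fold_plan([0, 1] * 5, k=5, seed=0)
        sizes = [len(plan.test_indices(f)) for f in range(5)]
        assert sizes == [2] * 5
        assert sorted(np.concatenate([plan.test_indices(f) for f in range(5)])) == list(range(10))

    def test_reproducible(self):
        labels = [0, 1] * 20
        a = ss.make_fold_plan(labels, seed=3)
        b = ss.make_fold_plan(labels, seed=3)
        assert np.array_equal(a.assignment, b.assignment)

    def test_rare_class_spread_across_folds(self):
        labels = [1] * 8 + [0] * 2
        with pytest.warns(UserWarning):
            plan = ss.make_fold_plan(labels, k=5, seed=0)
        zero_folds = plan.assignment[8:]
        assert zero_folds[0] != zero_folds[1]  # the two 0s land in different folds


class TestUndersampling:
    def _ds(self, counts):
        items = []
        for cls, n in counts.items():
            items += [(f"C{cls}_{i}", cls) for i in range(n)]
        return ss.CuratedDataset("multiclass", "WES", items)

    def test_majority_reduced_to_second_largest(self):
        out = ss.undersample_majority(self._ds({0: 5, 1: 15, 2: 4}), seed=0)
        assert out.class_counts() == {0: 5, 1: 5, 2: 4}

    def test_balanced_input_unchanged(self):
        ds = self._ds({0: 4, 1: 4, 2: 4})
        assert ss.undersample_majority(ds, seed=0).items == ds.items

    def test_only_majority_members_removed(self):
        ds = self._ds({0: 5, 1: 15, 2: 4})
        out = ss.undersample_majority(ds, seed=1)
        removed = set(s for s, _ in ds.items) - set(s for s, _ in out.items)
        assert all(s.startswith("C1_") for s in removed)

    def test_reproducible(self):
        ds = self._ds({0: 5, 1: 15, 2: 4})
        assert ss.undersample_majority(ds, seed=2).items == ss.undersample_majority(ds, seed=2).items


class TestMetrics:
    def test_confusion_counts_exhaustive(self):
        c = ss.confusion_counts([1, 1, 0, 0], [1, 0, 0, 1])
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)
        assert c.total == 4

    def test_perfect_and_inverted(self):
        perfect = ss.confusion_counts([1, 0], [1, 0])
        assert perfect.fp == perfect.fn == 0
        inverted = ss.confusion_counts([1, 0], [0, 1])
        assert inverted.tp == inverted.tn == 0

    def test_label_outside_binary_domain(self):
        with pytest.raises(ValueError):
            ss.confusion_counts([0, 2], [0, 1])

    def test_binary_metrics_formulas(self):
        rep = ss.binary_metrics(ConfusionCounts(tp=84, fn=16, tn=63, fp=37))
        assert rep.se == pytest.approx(0.84)
        assert rep.sp == pytest.approx(0.63)
        assert rep.ccr == pytest.approx(0.735)

    def test_undefined_metric_is_none_not_zero(self):
        rep = ss.binary_metrics(ConfusionCounts(tp=0, fn=5, tn=5, fp=0))
        assert rep.ppv is None and rep.se == 0.0

    def test_against_counting_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 200))
            y = rng.integers(0, 2, n)
            calls = rng.integers(0, 2, n)
            rep = ss.binary_metrics(ss.confusion_counts(y, calls))
            assert (rep.se, rep.sp, rep.ccr, rep.ppv, rep.npv) == brute_force_binary_metrics(
                y.tolist(), calls.tolist()
            )

    def test_multiclass_one_vs_rest_macro(self):
        rep = ss.multiclass_metrics([0, 1, 2, 2], [0, 2, 2, 2])
        assert rep.se == pytest.approx(2 / 3)
        assert rep.sp == pytest.approx((1 + 1 + 0.5) / 3)
        assert rep.ccr == pytest.approx(0.75)

    def test_multiclass_perfect(self):
        rep = ss.multiclass_metrics([0, 1, 2], [0, 1, 2])
        assert rep.se == rep.sp == rep.ccr == rep.ppv == rep.npv == 1.0

    def test_auc_examples(self):
        assert ss.auc_score([1, 0, 1, 0], [0.9, 0.1, 0.8, 0.2]) == 1.0
        assert ss.auc_score([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5]) == 0.5
        # 4 positive-negative pairs, one misranked (0.7 vs 0.8): 3/4
        assert ss.auc_score([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1]) == pytest.approx(0.75)
        # one tied pair counts half: 3.5/4
        assert ss.auc_score([1, 0, 1, 0], [0.9, 0.8, 0.8, 0.1]) == pytest.approx(0.875)
        assert ss.auc_score([1, 1], [0.3, 0.4]) is None


class TestTraining:
    @pytest.mark.parametrize("algorithm", ["random_forest", "lightgbm", "svm"])
    def test_probabilities_sum_to_one(self, algorithm, rng):
        X = rng.random((40, 5))
        y = (X[:, 0] > 0.5).astype(int)
        model = ss.train(X, y, algorithm, seed=0)
        proba = model.predict_proba(X)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_separable_data_learned_perfectly(self, rng):
        X = np.vstack([rng.random((20, 3)), rng.random((20, 3)) + 5])
        y = np.array([0] * 20 + [1] * 20)
        model = ss.train(X, y, "random_forest", seed=0)
        calls = (model.predict_proba(X)[:, 1] >= 0.5).astype(int)
        assert ss.modeling.ccr_score(y, calls) == 1.0

    def test_single_class_is_error(self):
        with pytest.raises(ValueError):
            ss.train(np.zeros((5, 2)), np.ones(5), "random_forest")

    def test_deterministic_given_seed(self, rng):
        X = rng.random((30, 4))
        y = rng.integers(0, 2, 30)
        p1 = ss.train(X, y, "random_forest", seed=1).predict_proba(X)
        p2 = ss.train(X, y, "random_forest", seed=1).predict_proba(X)
        assert np.array_equal(p1, p2)


class TestTuning:
    def test_single_trial_returns_default(self, rng):
        X = rng.random((30, 4))
        y = rng.integers(0, 2, 30)
        hp = ss.tune_hyperparameters(X, y, "random_forest", n_trials=1, seed=0)
        assert hp == default_hyperparameters("random_forest", X)

    def test_never_below_default_objective(self, rng):
        X = rng.random((60, 6))
        y = (X[:, 0] + 0.3 * rng.standard_normal(60) > 0.5).astype(int)
        hp = ss.tune_hyperparameters(X, y, "random_forest", n_trials=5, seed=0)
        obj_hp = _inner_cv_ccr(X, y, "random_forest", hp, "binary", seed=0)
        obj_default = _inner_cv_ccr(
            X, y, "random_forest", default_hyperparameters("random_forest", X), "binary", seed=0
        )
        assert obj_hp >= obj_default - 1e-12

    def test_within_search_space_and_reproducible(self, rng):
        X = rng.random((40, 5))
        y = rng.integers(0, 2, 40)
        a = ss.tune_hyperparameters(X, y, "svm", n_trials=4, seed=2)
        b = ss.tune_hyperparameters(X, y, "svm", n_trials=4, seed=2)
        assert a == b
        lo, hi = ss.modeling.SEARCH_SPACES["svm"]["C"][:2]
        assert lo <= a["C"] <= hi

    def test_unknown_algorithm_is_error(self):
        with pytest.raises(ValueError):
            ss.tune_hyperparameters(np.zeros((4, 2)), [0, 1, 0, 1], "mlp")


class TestCrossvalidate:
    def test_every_compound_scored_once(self, study_cv, study_binary):
        preds = study_cv.predictions
        assert len(preds) == len(study_binary.items)
        assert preds["scored"].all()
        # out-of-fold: each compound predicted by the model not trained on it
        assert set(preds["fold"]) == set(range(5))

    def test_ccr_identity_everywhere(self, study_cv):
        reports = [study_cv.pooled] + study_cv.fold_reports
        for rep in reports:
            if rep.se is not None and rep.sp is not None:
                assert rep.ccr == pytest.approx((rep.se + rep.sp) / 2)

    def test_calls_consistent_with_threshold(self, study_cv):
        preds = study_cv.predictions
        expected = (preds["prob"].to_numpy() >= study_cv.pt).astype(int)
        assert np.array_equal(preds["call"].to_numpy(), expected)

    def test_coverage_definition(self, study_cv):
        preds = study_cv.predictions
        assert study_cv.pooled.coverage == pytest.approx(
            100.0 * preds["in_ad"].sum() / len(preds)
        )


def test_y_randomize_returns_one_report_per_round(study_binary):
    config = ss.RunConfig(task="binary", feature_kind="ecfp4", algorithm="random_forest", seed=7)
    reports = ss.y_randomize(study_binary, config, rounds=2, seed=1)
    assert len(reports) == 2
    assert all(r.ccr is not None for r in reports)
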