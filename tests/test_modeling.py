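import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.dummy import DummyClassifier
from sklearn.tree import DecisionTreeClassifier

from appmarker.feature_selection import make_ig
from appmarker.modeling import (
    EvalReport,
    FoldResult,
    ModelSpec,
    TuningConfig,
    appearance_frequency,
    attributions,
    balanced_accuracy,
    default_zoo,
    fit_fold,
    fold_seed,
    metrics,
    nested_lopocv,
    rank_models,
    report_from_predictions,
    stack_top5,
)


class TestMetrics:
    def test_dummy_baseline_row(self):
        # constant-positive classifier on a 51/49 cohort
        r = metrics(tp=51, fp=49, tn=0, fn=0)
        assert r.precision == pytest.approx(0.510, abs=5e-4)
        assert r.sensitivity == 1.0
        assert r.f1 == pytest.approx(0.675, abs=5e-4)
        assert r.specificity == 0.0

    def test_balanced_accuracy_worked_example(self):
        assert balanced_accuracy(0.824, 0.714) == pytest.approx(0.769)

    def test_chance_level(self):
        r = metrics(tp=10, fn=10, tn=7, fp=7)
        assert r.balanced_accuracy == 0.5

    def test_zero_denominator_conventions(self):
        r = metrics(tp=0, fp=0, tn=5, fn=5)
        assert r.precision == 0.0 and r.sensitivity == 0.0 and r.f1 == 0.0

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            metrics(0, 0, 0, 0)
        with pytest.raises(ValueError):
            metrics(-1, 1, 1, 1)

    @given(
        st.integers(0, 100), st.integers(0, 100),
        st.integers(0, 100), st.integers(0, 100),
    )
    @settings(max_examples=200)
    def test_ranges_and_f1_bound(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        r = metrics(tp, fp, tn, fn)
        for v in (r.precision, r.sensitivity, r.specificity, r.f1,
                  r.accuracy, r.balanced_accuracy):
            assert 0.0 <= v <= 1.0
        assert r.f1 <= max(r.precision, r.sensitivity) + 1e-12

    def test_report_from_predictions_with_auc(self):
        r = report_from_predictions([1, 1, 0, 0], [1, 0, 0, 0], [0.9, 0.6, 0.4, 0.1])
        assert (r.tp, r.fn, r.tn, r.fp) == (1, 1, 2, 0)
        assert r.auc == 1.0


def separable_matrix(n=16, seed=0):
    """Perfectly separable toy matrix: one separating column + noise."""
    rng = np.random.default_rng(seed)
    pids = [f"p{i:02d}" for i in range(n)]
    y = np.array([i % 2 for i in range(n)])
    df = pd.DataFrame(
        {
            "sep": y * 4.0 - 2.0 + rng.normal(scale=0.05, size=n),
            "noise1": rng.normal(size=n),
            "noise2": rng.normal(size=n),
        },
        index=pids,
    )
    labels = dict(zip(pids, (int(v) for v in y)))
    return df, labels


SMALL_ZOO = default_zoo(["dummy", "logit", "knn"])


class TestNestedLopocv:
    def test_separable_cohort_perfect_accuracy(self):
        df, labels = separable_matrix()
        result = nested_lopocv(
            df, labels, make_ig(2), zoo=SMALL_ZOO,
            tuning=TuningConfig(budget=0), seed=0,
        )
        for name in ("logit", "knn"):
            assert result.reports[name].accuracy == 1.0

    def test_dummy_predicts_all_positive(self):
        df, labels = separable_matrix()
        result = nested_lopocv(
            df, labels, make_ig(2), zoo=SMALL_ZOO,
            tuning=TuningConfig(budget=0), seed=0,
        )
        r = result.reports["dummy"]
        assert r.sensitivity == 1.0 and r.specificity == 0.0
        assert r.precision == pytest.approx(sum(labels.values()) / len(labels))

    def test_reproducible_bit_for_bit(self):
        df, labels = separable_matrix()
        r1 = nested_lopocv(df, labels, make_ig(2), zoo=SMALL_ZOO,
                           tuning=TuningConfig(budget=2, inner_folds=4), seed=5)
        r2 = nested_lopocv(df, labels, make_ig(2), zoo=SMALL_ZOO,
                           tuning=TuningConfig(budget=2, inner_folds=4), seed=5)
        assert r1.reports == r2.reports
        assert [f.selected for f in r1.folds] == [f.selected for f in r2.folds]
        assert [f.params for f in r1.folds] == [f.params for f in r2.folds]

    def test_needs_two_per_class(self):
        df, labels = separable_matrix(n=6)
        labels = {p: (1 if i == 0 else 0) for i, p in enumerate(df.index)}
        with pytest.raises(ValueError):
            nested_lopocv(df, labels, make_ig(2), zoo=SMALL_ZOO)

    def test_inner_folds_reduced_for_small_classes(self):
        # 20-fold inner CV is impossible with 8 per class: must still run
        df, labels = separable_matrix(n=16)
        result = nested_lopocv(
            df, labels, make_ig(2), zoo=default_zoo(["logit"]),
            tuning=TuningConfig(budget=2, inner_folds=20), seed=0,
        )
        assert result.reports["logit"].accuracy == 1.0


class TestLeakage:
    def test_fold_artifacts_unchanged_when_heldout_row_deleted(self):
        df, labels = separable_matrix(n=14, seed=3)
        heldout = df.index[4]
        train_full = df.drop(index=heldout)
        y_train = pd.Series({p: labels[p] for p in train_full.index})
        zoo = default_zoo(["logit", "knn"])
        tuning = TuningConfig(budget=3, inner_folds=5)
        seed = fold_seed(11, heldout)
        fit_a = fit_fold(train_full, y_train, make_ig(2), zoo, tuning, seed)
        # delete the held-out row from the cohort entirely and recompute
        fit_b = fit_fold(df.drop(index=heldout), y_train, make_ig(2), zoo, tuning, seed)
        pd.testing.assert_series_equal(fit_a.scaler_mean, fit_b.scaler_mean)
        pd.testing.assert_series_equal(fit_a.scaler_sd, fit_b.scaler_sd)
        assert fit_a.selected == fit_b.selected
        assert fit_a.params == fit_b.params

    def test_fold_seed_stable(self):
        assert fold_seed(7, "p01") == fold_seed(7, "p01")
        assert fold_seed(7, "p01") != fold_seed(8, "p01")


def _constant_spec(name, constant):
    return ModelSpec(
        name, lambda seed, c=constant: DummyClassifier(strategy="constant", constant=c), {}
    )


def _tree_spec(name):
    return ModelSpec(name, lambda seed: DecisionTreeClassifier(random_state=seed), {})


class TestStacking:
    def test_identical_base_learners_match_single_learner(self):
        df, labels = separable_matrix(n=16)
        zoo = {f"tree{i}": _tree_spec(f"tree{i}") for i in range(5)}
        result = nested_lopocv(df, labels, make_ig(2), zoo=zoo,
                               tuning=TuningConfig(budget=0), seed=0)
        report, top = stack_top5(df, labels, result, zoo=zoo, seed=0)
        single = result.reports["tree0"]
        assert report.accuracy == single.accuracy == 1.0

    def test_mixed_base_learners_on_separable_data(self):
        # always-positive, always-negative and 3 perfect learners
        df, labels = separable_matrix(n=16)
        zoo = {
            "allpos": _constant_spec("allpos", 1),
            "allneg": _constant_spec("allneg", 0),
            "tree0": _tree_spec("tree0"),
            "tree1": _tree_spec("tree1"),
            "tree2": _tree_spec("tree2"),
        }
        result = nested_lopocv(df, labels, make_ig(2), zoo=zoo,
                               tuning=TuningConfig(budget=0), seed=0)
        report, _ = stack_top5(df, labels, result, zoo=zoo, seed=0)
        assert report.accuracy == 1.0

    def test_stacking_beats_dummy(self):
        df, labels = separable_matrix(n=16)
        zoo = default_zoo(["dummy", "logit", "knn", "decision_tree",
                           "gaussian_nb", "extra_trees"])
        result = nested_lopocv(df, labels, make_ig(2), zoo=zoo,
                               tuning=TuningConfig(budget=0), seed=0)
        report, top = stack_top5(df, labels, result, zoo=zoo, seed=0)
        assert "dummy" not in top
        assert report.f1 >= result.reports["dummy"].f1

    def test_requires_five_models(self):
        df, labels = separable_matrix(n=16)
        result = nested_lopocv(df, labels, make_ig(2), zoo=SMALL_ZOO,
                               tuning=TuningConfig(budget=0), seed=0)
        with pytest.raises(ValueError):
            stack_top5(df, labels, result, zoo=SMALL_ZOO, seed=0)


def test_rank_models_tie_break():
    r_hi = metrics(tp=10, fp=0, tn=10, fn=0)
    r_lo = metrics(tp=5, fp=5, tn=5, fn=5)
    reports = {"b": r_hi, "a": r_hi, "c": r_lo, "dummy": r_lo}
    assert rank_models(reports) == ["a", "b", "c"]


class TestAppearanceFrequency:
    def test_always_and_never(self):
        folds = [
            FoldResult(f"p{i}", ["always"] + (["sometimes"] if i < 49 else []), {}, {})
            for i in range(100)
        ]
        freq = appearance_frequency(folds)
        assert freq["always"] == 100.0
        assert freq["sometimes"] == 49.0
        assert "never" not in freq

    def test_98_of_100(self):
        folds = [FoldResult(f"p{i}", ["f"] if i < 98 else [], {}, {}) for i in range(100)]
        assert appearance_frequency(folds)["f"] == 98.0

    def test_empty(self):
        assert appearance_frequency([]).empty


class TestAttributions:
    def test_constant_model_all_zero(self):
        df, labels = separable_matrix(n=16)
        y = [labels[p] for p in df.index]
        model = DummyClassifier(strategy="constant", constant=1).fit(df, y)
        table = attributions(model, df, y, seed=0)
        assert (table["importance_mean"] == 0.0).all()

    def test_single_feature_model_concentrates_mass(self):
        df, labels = separable_matrix(n=20)
        y = [labels[p] for p in df.index]
        model = DecisionTreeClassifier(max_depth=1, random_state=0).fit(df, y)
        table = attributions(model, df, y, seed=0).set_index("feature")
        assert table["importance_mean"]["sep"] > 0.4
        assert table["importance_mean"].drop("sep").abs().max() == 0.0
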