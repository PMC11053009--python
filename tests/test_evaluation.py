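import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.datasets import make_blobs

from cardiokit.core import ConfusionCounts
from cardiokit.evaluation import (
    ClassifierSpec,
    average_performance,
    confusion_metrics,
    difference_ratio,
    entropy_report,
    performance_entropy,
    split_and_cv,
)
from cardiokit.reported import ARRHYTHMIA_METRICS, HEART_DISEASE_METRICS


class TestConfusionMetrics:
    def test_direct_substitution(self):
        m = confusion_metrics(ConfusionCounts(tp=90, fn=10, tn=80, fp=20))
        assert m["Se"] == pytest.approx(0.9)
        assert m["Sp"] == pytest.approx(0.8)
        assert m["AUC"] == pytest.approx(0.85)
        assert m["FPR"] == pytest.approx(0.2)

    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionCounts(50, 50, 0, 0))
        assert m["ACC"] == 1.0 and m["MCC"] == 1.0 and m["DER"] == 0.0

    def test_anti_classifier(self):
        m = confusion_metrics(ConfusionCounts(0, 0, 50, 50))
        assert m["ACC"] == 0.0 and m["MCC"] == -1.0

    def test_undefined_entries_are_nan(self):
        m = confusion_metrics(ConfusionCounts(tp=0, tn=10, fp=0, fn=0))
        assert np.isnan(m["Prec"]) and np.isnan(m["Se"])

    @given(st.integers(1, 500), st.integers(1, 500), st.integers(1, 500), st.integers(1, 500))
    def test_internal_consistency(self, tp, tn, fp, fn):
        m = confusion_metrics(ConfusionCounts(tp, tn, fp, fn))
        assert m["AUC"] == pytest.approx((m["Se"] + m["Sp"]) / 2)
        assert m["Sp"] == pytest.approx(1 - m["FPR"])
        assert m["F1"] == pytest.approx(2 / (1 / m["Prec"] + 1 / m["Se"]))
        assert m["G-mean"] == pytest.approx(np.sqrt(m["Prec"] * m["Se"]))
        assert m["DER"] == pytest.approx(1 - m["ACC"])


class TestTableArithmetic:
    @pytest.mark.parametrize(
        "clf, metric, expected",
        [
            ("nn", "ACC", 0.902),
            ("svm", "G-mean", 0.8635),
            ("rf", "Se", 0.891),
            ("nn", "G-mean", 0.822),
        ],
    )
    def test_cross_dataset_averages(self, clf, metric, expected):
        avg = average_performance(
            ARRHYTHMIA_METRICS.loc[clf], HEART_DISEASE_METRICS.loc[clf]
        )
        assert avg[metric] == pytest.approx(expected, abs=5e-4)

    def test_knn_accuracy_difference_ratio(self):
        avg = average_performance(
            ARRHYTHMIA_METRICS.loc["knn"], HEART_DISEASE_METRICS.loc["knn"]
        )
        assert difference_ratio(avg)["ACC"] == pytest.approx(0.158, abs=5e-4)

    def test_difference_ratio_fixed_points(self):
        s = pd.Series({"ACC": 1.0, "Se": 0.5, "Sp": 0.0})
        out = difference_ratio(s)
        assert out["ACC"] == 0.0 and out["Se"] == 0.5 and out["Sp"] == 1.0

    def test_difference_ratio_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            difference_ratio(pd.Series({"MCC": -0.2}))

    def test_average_of_identical_is_identity(self):
        row = ARRHYTHMIA_METRICS.loc["rf"]
        pd.testing.assert_series_equal(average_performance(row, row), row)

    def test_chain_identity(self):
        # difference_ratio(average(a, b)) == 1 - (a + b)/2 element-wise
        a, b = ARRHYTHMIA_METRICS.loc["nb"], HEART_DISEASE_METRICS.loc["nb"]
        chained = difference_ratio(average_performance(a, b))
        np.testing.assert_allclose(chained, 1 - (a + b) / 2, atol=1e-12)


class TestEntropy:
    def test_known_values(self):
        assert performance_entropy(0.5) == pytest.approx(1.0)
        assert performance_entropy(1.0) == 0.0
        assert performance_entropy(0.0) == 0.0
        # frozen from an independent high-precision evaluation of
        # -p*log2(p) - (1-p)*log2(1-p) at p = 0.937
        assert performance_entropy(0.937) == pytest.approx(0.3392404418, abs=1e-9)

    @given(st.floats(0.0, 1.0))
    def test_symmetry_and_bounds(self, p):
        h = performance_entropy(p)
        assert 0.0 <= h <= 1.0
        assert h == pytest.approx(performance_entropy(1.0 - p), abs=1e-12)

    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.99))
    def test_concavity(self, p, q):
        mid = performance_entropy((p + q) / 2)
        assert mid >= (performance_entropy(p) + performance_entropy(q)) / 2 - 1e-12

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            performance_entropy(1.2)

    def test_report_layout(self):
        report = entropy_report(ARRHYTHMIA_METRICS)
        assert set(report.columns) == {"classifier", "metric", "P_perf", "P_diff", "H_bits"}
        assert len(report) == ARRHYTHMIA_METRICS.size
        np.testing.assert_allclose(report["P_perf"] + report["P_diff"], 1.0)


@pytest.fixture(scope="module")
def blobs():
    return make_blobs(
        n_samples=200, centers=[[-3, -3], [3, 3]], cluster_std=1.0, random_state=0
    )


class TestSplitAndCV:

    @pytest.mark.parametrize("kind", ["knn", "svm", "rf", "nb"])
    def test_separable_blobs_high_accuracy(self, blobs, kind):
        X, y = blobs
        res = split_and_cv(X, y, ClassifierSpec(kind), ratio=0.8, folds=10, seed=0)
        assert res.metrics["ACC"] >= 0.95
        assert res.cv_mean >= 0.95

    def test_knn_one_neighbour_identity(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 3))
        y = np.array([0, 1] * 20)
        from cardiokit.evaluation import make_classifier

        model = make_classifier(ClassifierSpec("knn", k=1)).fit(X, y)
        assert model.predict(X[:1])[0] == y[0]

    def test_too_few_rows_per_class_rejected(self):
        X = np.zeros((18, 2))
        y = np.array([0] * 9 + [1] * 9)
        with pytest.raises(ValueError, match="fold"):
            split_and_cv(X, y, ClassifierSpec("nb"), folds=10)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            split_and_cv(np.zeros((30, 2)), np.zeros(30), ClassifierSpec("nb"))

    def test_seeded_runs_are_reproducible(self, blobs):
        X, y = blobs
        a = split_and_cv(X, y, ClassifierSpec("rf", seed=5), seed=5)
        b = split_and_cv(X, y, ClassifierSpec("rf", seed=5), seed=5)
        assert a.counts == b.counts
        np.testing.assert_array_equal(a.cv_accuracy, b.cv_accuracy)

    def test_multiclass_pooled_counts(self):
        rng = np.random.default_rng(2)
        X = np.concatenate([rng.normal(c, 0.3, size=(60, 2)) for c in (-4, 0, 4)])
        y = np.repeat(["a", "b", "c"], 60)
        res = split_and_cv(X, y, ClassifierSpec("knn"), folds=5, seed=1)
        assert res.counts.total == 36 * 3  # 36 held-out rows, one-vs-rest pooled
        assert res.metrics["ACC"] >= 0.95
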