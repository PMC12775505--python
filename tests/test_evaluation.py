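import numpy as np
import pytest
from scipy import stats

from fidgetlab import (aggregate_metrics, classification_metrics,
                       friedman_nemenyi, friedman_statistic, make_folds,
                       run_experiment)
from fidgetlab.config import (CohortConfig, EvalConfig, HCFConfig,
                              MBCNNTrainConfig, StudyConfig)
from fidgetlab.evaluation import MetricsRow


class TestMakeFolds:
    def test_risk_subjects_spread_evenly_95_6(self):
        subjects = [f"S{i:03d}" for i in range(95)]
        risk = {s: i < 6 for i, s in enumerate(subjects)}
        folds = make_folds(subjects, risk, n_folds=5, seed=0)
        risk_counts = sorted(
            sum(risk[s] for s in folds.fold_subjects(f)) for f in range(5))
        assert risk_counts == [1, 1, 1, 1, 2]
        sizes = [len(folds.fold_subjects(f)) for f in range(5)]
        assert max(sizes) - min(sizes) <= 1

    def test_five_subjects_five_folds(self):
        folds = make_folds([f"S{i}" for i in range(5)], {}, 5, seed=1)
        assert sorted(len(folds.fold_subjects(f)) for f in range(5)) == [1] * 5

    def test_partition_property(self):
        subjects = [f"S{i}" for i in range(23)]
        folds = make_folds(subjects, {s: i % 9 == 0 for i, s in
                                      enumerate(subjects)}, 5, seed=2)
        assert sorted(folds.assignment) == sorted(subjects)
        sizes = [len(folds.fold_subjects(f)) for f in range(5)]
        assert max(sizes) - min(sizes) <= 1

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b"], {}, 1, 0)
        with pytest.raises(ValueError):
            make_folds(["a", "a", "b", "c", "d"], {}, 2, 0)


class TestClassificationMetrics:
    def test_perfect_prediction(self):
        y = np.array([1, 0, 1, 1, 0])
        m = classification_metrics(y, y)
        assert (m.accuracy, m.af1, m.sensitivity, m.specificity,
                m.precision) == (100.0, 100.0, 100.0, 100.0, 100.0)

    def test_fixed_confusion_matrix_arithmetic(self):
        y_true = np.array([1] * 100 + [0] * 100)
        y_pred = np.array([1] * 90 + [0] * 10 + [1] * 60 + [0] * 40)
        m = classification_metrics(y_true, y_pred)
        assert m.accuracy == pytest.approx(65.00)
        assert m.sensitivity == pytest.approx(90.00)
        assert m.specificity == pytest.approx(40.00)
        assert m.precision == pytest.approx(60.00)
        assert m.af1 == pytest.approx(62.67, abs=0.005)

    def test_matches_naive_recount(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            y = rng.integers(0, 2, 50)
            p = rng.integers(0, 2, 50)
            m = classification_metrics(y, p)
            tp = int(((y == 1) & (p == 1)).sum())
            tn = int(((y == 0) & (p == 0)).sum())
            fp = int(((y == 0) & (p == 1)).sum())
            fn = int(((y == 1) & (p == 0)).sum())
            assert m.accuracy == pytest.approx(100 * (tp + tn) / 50,
                                               abs=1e-12)
            sens = tp / (tp + fn) if tp + fn else 0
            spec = tn / (tn + fp) if tn + fp else 0
            assert m.sensitivity == pytest.approx(100 * sens, abs=1e-12)
            assert m.specificity == pytest.approx(100 * spec, abs=1e-12)

    def test_no_positive_predictions_warns_zero_precision(self):
        with pytest.warns(UserWarning):
            m = classification_metrics([1, 0, 1], [0, 0, 0])
        assert m.precision == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics([], [])

    def test_aggregate_recomputable(self):
        rows = [MetricsRow(60, 55, 70, 40, 62), MetricsRow(70, 60, 72, 50,
                                                           64)]
        agg = aggregate_metrics(rows)
        assert agg["accuracy"][0] == pytest.approx(65.0)
        assert agg["accuracy"][1] == pytest.approx(np.std([60, 70], ddof=1))


class TestFriedmanNemenyi:
    def test_bonferroni_alpha_printed_value(self):
        table = np.random.default_rng(0).normal(size=(3, 5))
        rep = friedman_nemenyi(table, ["a", "b", "c"], alpha=0.05, n_tests=9)
        assert rep.corrected_alpha == 0.0056

    def test_identical_methods_give_zero_statistic(self):
        table = np.tile(np.arange(5.0), (3, 1))
        rep = friedman_nemenyi(table, list("abc"))
        assert rep.friedman_statistic == 0.0
        assert rep.friedman_p == 1.0

    def test_statistic_matches_textbook_rank_formula(self):
        rng = np.random.default_rng(1)
        table = rng.normal(size=(4, 6))  # continuous: no ties
        k, n = table.shape
        ranks = np.stack([stats.rankdata(table[:, j]) for j in range(n)], 1)
        rbar = ranks.mean(axis=1)
        expected = 12 * n / (k * (k + 1)) * np.sum(
            (rbar - (k + 1) / 2) ** 2)
        assert friedman_statistic(table) == pytest.approx(expected,
                                                          abs=1e-10)
        # and agrees with the scipy implementation
        chi_scipy, _ = stats.friedmanchisquare(*[table[i] for i in range(k)])
        assert friedman_statistic(table) == pytest.approx(chi_scipy,
                                                          abs=1e-10)

    def test_nemenyi_matrix_properties(self):
        rng = np.random.default_rng(2)
        table = rng.normal(size=(3, 8))
        table[0] += 5.0  # one clearly better method
        rep = friedman_nemenyi(table, list("abc"))
        P = rep.nemenyi_p
        assert np.allclose(P, P.T)
        assert np.all((P >= 0) & (P <= 1))
        assert np.array_equal(rep.significant, P < rep.corrected_alpha)

    def test_minimum_shape_enforced(self):
        with pytest.raises(ValueError):
            friedman_nemenyi(np.zeros((2, 5)), ["a", "b"])


class TestRunExperiment:
    def test_dry_run_plans_nine_jobs_of_five_folds(self):
        report = run_experiment(StudyConfig(), dry_run=True)
        assert report["n_jobs"] == 9
        assert report["n_trainings"] == 45
        assert all(job["folds"] == 5 for job in report["plan"])

    def test_tiny_smoke_run_aggregates_consistently(self):
        cfg = StudyConfig(
            cohort=CohortConfig(n_subjects=6, duration_fixed_s=30.0),
            hcf=HCFConfig(search_budget=1),
            mbcnn=MBCNNTrainConfig(epochs=1, batch_size=32,
                                   learning_rate=1e-3),
            csad=MBCNNTrainConfig(epochs=1, batch_size=32,
                                  learning_rate=1e-3),
            evaluation=EvalConfig(n_folds=2),
            seed=11,
        )
        report = run_experiment(cfg, approaches=("hcf", "mbcnn", "csad"),
                                modalities=("imu",))
        for key, tab in report["tables"].items():
            assert len(tab["test"]) == 2
            agg = aggregate_metrics(tab["test"])
            assert tab["test_aggregate"]["accuracy"][0] == pytest.approx(
                agg["accuracy"][0])
        assert "test_af1" in report["stats"]
        assert report["stats"]["test_af1"].corrected_alpha == pytest.approx(
            round(0.05 / 3, 4))
        assert report["n_windows"] > 100
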