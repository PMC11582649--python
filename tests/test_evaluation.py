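import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tileshot import (
    BootstrapCI,
    EvaluationTask,
    ModelResult,
    ResultLog,
    bootstrap_ci,
    compare_runs,
    confusion_matrix,
    outcome_fixture,
    per_label_recall,
    score,
)
from tileshot.evaluation import COUNT_AS_WRONG, EXCLUDE
from tileshot.prompting import FAILED, OK, UNMAPPED


def _log(outcomes, failures=0, unmapped=0, metadata=None):
    """Build a ResultLog from (truth, answer) pairs plus bad records."""
    log = ResultLog(metadata=metadata or {})
    i = 0
    for truth, answer in outcomes:
        log.append(
            EvaluationTask(f"task{i}", f"tile{i}", truth),
            ModelResult("because", answer, 0.9, "raw", OK),
        )
        i += 1
    for _ in range(failures):
        log.append(
            EvaluationTask(f"task{i}", f"tile{i}", "A"),
            ModelResult("", None, None, "refused", FAILED),
        )
        i += 1
    for _ in range(unmapped):
        log.append(
            EvaluationTask(f"task{i}", f"tile{i}", "A"),
            ModelResult("x", None, 0.2, "raw", UNMAPPED),
        )
        i += 1
    return log


class TestScore:
    def test_counts_correct_and_wrong(self):
        pairs = [("A", "A")] * 54 + [("A", "B")] * 6
        vec = score(_log(pairs))
        assert vec.n == 60
        assert int(vec.values.sum()) == 54

    def test_exclude_policy_drops_failures(self):
        vec = score(_log([("A", "A")] * 58, failures=2), EXCLUDE)
        assert vec.n == 58
        assert vec.n_failed == 2

    def test_count_as_wrong_policy_forces_zeros(self):
        vec = score(_log([("A", "A")] * 58, failures=2), COUNT_AS_WRONG)
        assert vec.n == 60
        assert int(vec.values.sum()) == 58

    def test_unmapped_tracked_separately(self):
        vec = score(_log([("A", "A")] * 5, unmapped=3))
        assert vec.n_unmapped == 3
        assert vec.n_failed == 0

    def test_empty_log_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            score(ResultLog())


class TestBootstrapCI:
    def test_all_correct_degenerate(self):
        ci = bootstrap_ci(outcome_fixture(60, 60), seed=0)
        assert (ci.lower, ci.point, ci.upper) == (1.0, 1.0, 1.0)

    def test_reproduces_printed_ten_shot_bounds(self):
        """54/60 successes: percentile bounds land on 49/60 and 58/60."""
        ci = bootstrap_ci(outcome_fixture(54, 60), seed=3)
        assert round(ci.lower, 3) == 0.817
        assert round(ci.upper, 3) == 0.967

    def test_reproduces_printed_mhist_lower_bound(self):
        ci = bootstrap_ci(outcome_fixture(50, 60), seed=3)
        assert round(ci.lower, 3) == 0.733
        assert round(ci.upper, 3) == 0.917

    def test_agrees_with_exact_binomial_quantile_oracle(self):
        """The resampled mean of a binary vector is Binomial(n, p)/n, so
        the percentile bounds must converge to exact binomial quantiles.
        Configurations are screened so the target quantile is not on a
        knife edge (tail probability >= 0.005 away from alpha/2)."""
        rng = np.random.default_rng(12)
        checked = 0
        trials = 0
        while checked < 30 and trials < 300:
            trials += 1
            n = int(rng.integers(20, 201))
            k = int(rng.integers(1, n))
            p = k / n
            lo_exact = stats.binom.ppf(0.025, n, p) / n
            hi_exact = stats.binom.ppf(0.975, n, p) / n
            # knife-edge screen on both tails
            lo_cdf = stats.binom.cdf(lo_exact * n, n, p)
            lo_cdf_prev = stats.binom.cdf(lo_exact * n - 1, n, p)
            hi_cdf = stats.binom.cdf(hi_exact * n, n, p)
            hi_cdf_prev = stats.binom.cdf(hi_exact * n - 1, n, p)
            if (
                abs(lo_cdf - 0.025) < 0.005
                or abs(lo_cdf_prev - 0.025) < 0.005
                or abs(hi_cdf - 0.975) < 0.005
                or abs(hi_cdf_prev - 0.975) < 0.005
            ):
                continue
            ci = bootstrap_ci(outcome_fixture(k, n), seed=trials)
            assert ci.lower == pytest.approx(lo_exact, abs=1e-12), (n, k)
            assert ci.upper == pytest.approx(hi_exact, abs=1e-12), (n, k)
            checked += 1
        assert checked == 30

    def test_ordering_and_width_shrinks_with_n(self):
        widths = []
        for n in (30, 60, 120, 1000):
            k = int(round(0.8 * n))
            ci = bootstrap_ci(outcome_fixture(k, n), seed=5)
            assert ci.lower <= ci.point <= ci.upper
            widths.append(ci.upper - ci.lower)
        assert widths == sorted(widths, reverse=True)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.array([]), seed=0)

    def test_stratified_variant_available(self):
        log = _log([("A", "A")] * 20 + [("B", "B")] * 15 + [("B", "A")] * 5)
        vec = score(log)
        ci = bootstrap_ci(vec, seed=2, stratify_by_label=True)
        assert ci.lower <= ci.point <= ci.upper

    def test_invalid_ci_ordering_rejected(self):
        with pytest.raises(ValueError):
            BootstrapCI(point=0.5, lower=0.6, upper=0.9, iterations=10, seed=0)


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        log = _log([("A", "A")] * 3 + [("B", "B")] * 2)
        mat = confusion_matrix(log, ["A", "B"])
        assert mat.values.tolist() == [[3, 0], [0, 2]]

    def test_single_predicted_class_single_column(self):
        log = _log([("A", "B"), ("B", "B"), ("A", "B")])
        mat = confusion_matrix(log, ["A", "B"])
        assert mat["A"].sum() == 0
        assert mat["B"].sum() == 3

    def test_known_counts_tally(self):
        pairs = (
            [("A", "A")] * 4 + [("A", "C")] * 2
            + [("B", "B")] * 5 + [("C", "A")] * 1 + [("C", "C")] * 3
        )
        mat = confusion_matrix(_log(pairs), ["A", "B", "C"])
        assert mat.loc["A", "A"] == 4
        assert mat.loc["A", "C"] == 2
        assert mat.loc["C", "A"] == 1
        assert int(mat.values.sum()) == len(pairs)

    def test_row_sums_equal_per_label_counts(self):
        pairs = [("A", "B")] * 7 + [("B", "B")] * 9
        mat = confusion_matrix(_log(pairs), ["A", "B"])
        assert mat.loc["A"].sum() == 7
        assert mat.loc["B"].sum() == 9


class TestPerLabelRecall:
    def test_diagonal_matrix_all_ones(self):
        mat = pd.DataFrame([[5, 0], [0, 7]], index=["A", "B"], columns=["A", "B"])
        recalls, macro = per_label_recall(mat)
        assert recalls == {"A": 1.0, "B": 1.0}
        assert macro == 1.0

    def test_fully_misassigned_class_zero(self):
        mat = pd.DataFrame([[0, 5], [0, 7]], index=["A", "B"], columns=["A", "B"])
        recalls, _ = per_label_recall(mat)
        assert recalls["A"] == 0.0

    def test_mixed_recalls_and_macro(self):
        mat = pd.DataFrame([[24, 6], [0, 30]], index=["A", "B"], columns=["A", "B"])
        recalls, macro = per_label_recall(mat)
        assert recalls == {"A": 0.8, "B": 1.0}
        assert macro == pytest.approx(0.9)

    def test_empty_row_flagged_and_excluded(self):
        mat = pd.DataFrame([[3, 0], [0, 0]], index=["A", "B"], columns=["A", "B"])
        with pytest.warns(UserWarning, match="'B'"):
            recalls, macro = per_label_recall(mat)
        assert "B" not in recalls
        assert macro == 1.0


class TestCompareRuns:
    def _meta(self, k):
        return {"dataset": "fix", "sampler": "knn", "k": k}

    def test_identical_runs_identical_rows(self):
        pairs = [("A", "A")] * 10 + [("A", "B")] * 2
        t = compare_runs(
            [_log(pairs, metadata=self._meta(3)), _log(pairs, metadata=self._meta(3))],
            iterations=2000,
            seed=4,
        )
        assert t.iloc[0].equals(t.iloc[1])

    def test_monotone_accuracy_column_from_constructed_runs(self):
        logs = [
            _log([("A", "A")] * h + [("A", "B")] * (20 - h),
                 metadata=self._meta(k))
            for k, h in [(0, 10), (3, 14), (5, 17), (10, 20)]
        ]
        t = compare_runs(logs, iterations=2000, seed=4)
        acc = t.sort_values("shots")["accuracy"].tolist()
        assert acc == sorted(acc)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compare_runs([])

    def test_mismatched_task_sets_warn_with_intersection(self):
        a = _log([("A", "A")] * 5, metadata=self._meta(1))
        b = _log([("A", "A")] * 8, metadata=self._meta(2))
        with pytest.warns(UserWarning, match="intersection size 5"):
            compare_runs([a, b], iterations=500, seed=0)


class TestResultLogIO:
    def test_jsonl_roundtrip(self, tmp_path, mock_run):
        log = mock_run(k=1)
        p = tmp_path / "run.jsonl"
        log.to_jsonl(p)
        back = ResultLog.from_jsonl(p)
        assert back.metadata == log.metadata
        assert len(back) == len(log)
        assert [r.result.answer for r in back.records] == [
            r.result.answer for r in log.records
        ]
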