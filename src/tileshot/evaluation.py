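"""Scoring, confusion matrices, and percentile-bootstrap confidence intervals.

Accuracy on the small balanced test sets (n = 60 or 120 tasks) is reported
as a point estimate with lower/upper 2.5% percentile bounds from 100,000
bootstrap resamples of the binary outcome vector.  Because each resampled
mean of a binary vector is k/n for some integer k, the percentile is taken
as an empirical order statistic without interpolation, so reported bounds
always lie on the k/n lattice; the exact Binomial(n, p-hat)/n quantile is
the convergence limit and serves as an independent oracle in tests.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import EvaluationTask
from .prompting import FAILED, OK, UNMAPPED, ModelResult

EXCLUDE = "exclude"
COUNT_AS_WRONG = "count-as-wrong"

DEFAULT_BOOTSTRAP_ITERATIONS = 100_000


@dataclass
class TaskOutcome:
    """One scored task: what was asked, what came back."""

    task: EvaluationTask
    result: ModelResult
    context_summary: dict | None = None
    timestamp: str = ""


@dataclass
class ResultLog:
    """All task outcomes of one run plus the metadata to reproduce it."""

    records: list[TaskOutcome] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def append(self, task, result, context_summary=None) -> None:
        self.records.append(
            TaskOutcome(
                task,
                result,
                context_summary,
                timestamp=datetime.now(timezone.utc).isoformat(),
            )
        )

    def __len__(self) -> int:
        return len(self.records)

    def to_jsonl(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with path.open("w") as fh:
            fh.write(json.dumps({"metadata": self.metadata}) + "\n")
            for rec in self.records:
                fh.write(
                    json.dumps(
                        {
                            "task_id": rec.task.task_id,
                            "target": rec.task.target_tile_id,
                            "truth": rec.task.truth,
                            "answer": rec.result.answer,
                            "score": rec.result.score,
                            "thoughts": rec.result.thoughts,
                            "parse_status": rec.result.status,
                            "context": rec.context_summary,
                            "raw": rec.result.raw,
                            "timestamp": rec.timestamp,
                        }
                    )
                    + "\n"
                )

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "ResultLog":
        log = cls()
        with Path(path).open() as fh:
            first = json.loads(fh.readline())
            log.metadata = first.get("metadata", {})
            for line in fh:
                d = json.loads(line)
                log.records.append(
                    TaskOutcome(
                        EvaluationTask(d["task_id"], d["target"], d["truth"]),
                        ModelResult(
                            d.get("thoughts", ""),
                            d.get("answer"),
                            d.get("score"),
                            d.get("raw", ""),
                            d.get("parse_status", OK),
                        ),
                        d.get("context"),
                        d.get("timestamp", ""),
                    )
                )
        return log


@dataclass
class OutcomeVector:
    """Binary correctness indicators for the scored tasks of a run."""

    values: np.ndarray  # 1 = correct, 0 = wrong
    labels: list[str]  # ground-truth label per scored task
    n_failed: int = 0
    n_unmapped: int = 0
    failure_policy: str = EXCLUDE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 1:
            raise ValueError("outcome vector must be 1-D")
        if len(self.labels) != len(self.values):
            raise ValueError("labels length must match outcome length")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def accuracy(self) -> float:
        return float(self.values.mean())


def score(log: ResultLog, failure_policy: str = EXCLUDE) -> OutcomeVector:
    """Turn a result log into a binary outcome vector.

    Records whose response failed to parse or mapped to no label are either
    dropped (``exclude``; the counts are kept on the vector) or scored as
    incorrect (``count-as-wrong``).
    """
    if failure_policy not in (EXCLUDE, COUNT_AS_WRONG):
        raise ValueError(f"unknown failure policy {failure_policy!r}")
    if not log.records:
        raise ValueError("result log is empty")
    values: list[int] = []
    labels: list[str] = []
    n_failed = n_unmapped = 0
    for rec in log.records:
        status = rec.result.status
        if status == FAILED:
            n_failed += 1
        elif status == UNMAPPED:
            n_unmapped += 1
        if status != OK:
            if failure_policy == COUNT_AS_WRONG:
                values.append(0)
                labels.append(rec.task.truth)
            continue
        values.append(int(rec.result.answer == rec.task.truth))
        labels.append(rec.task.truth)
    return OutcomeVector(
        np.array(values, dtype=np.int8),
        labels,
        n_failed=n_failed,
        n_unmapped=n_unmapped,
        failure_policy=failure_policy,
    )


@dataclass(frozen=True)
class BootstrapCI:
    """Point accuracy with percentile-bootstrap bounds."""

    point: float
    lower: float
    upper: float
    iterations: int
    seed: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.point <= self.upper <= 1.0):
            raise ValueError(
                f"invalid CI ordering: {self.lower} <= {self.point} <= {self.upper}"
            )


def bootstrap_ci(
    outcomes: OutcomeVector | np.ndarray | Sequence[int],
    iterations: int = DEFAULT_BOOTSTRAP_ITERATIONS,
    alpha: float = 0.05,
    seed: int = 0,
    stratify_by_label: bool = False,
) -> BootstrapCI:
    """Percentile bootstrap CI of the mean of a binary outcome vector.

    Draws ``iterations`` resamples of size n with replacement, takes the
    mean of each, and reports the empirical order statistics at ranks
    ceil(alpha/2 * B) and ceil((1 - alpha/2) * B) (no interpolation, so
    bounds sit on the k/n lattice).  ``stratify_by_label`` resamples within
    each ground-truth label instead of from the pooled vector; the default
    is pooled.
    """
    if isinstance(outcomes, OutcomeVector):
        values = outcomes.values.astype(np.float64)
        labels = outcomes.labels
    else:
        values = np.asarray(outcomes, dtype=np.float64)
        labels = None
    n = values.size
    if n < 1:
        raise ValueError("outcome vector is empty")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if stratify_by_label:
        if labels is None:
            raise ValueError("stratified bootstrap needs per-task labels")
        groups = [values[np.asarray(labels) == lab] for lab in sorted(set(labels))]
        totals = np.zeros(iterations)
        for g in groups:
            idx = rng.integers(0, g.size, size=(iterations, g.size))
            totals += g[idx].sum(axis=1)
        means = totals / n
    else:
        idx = rng.integers(0, n, size=(iterations, n))
        means = values[idx].mean(axis=1)
    means.sort()
    lo_rank = max(math.ceil(alpha / 2 * iterations), 1)
    hi_rank = min(math.ceil((1 - alpha / 2) * iterations), iterations)
    return BootstrapCI(
        point=float(values.mean()),
        lower=float(means[lo_rank - 1]),
        upper=float(means[hi_rank - 1]),
        iterations=iterations,
        seed=seed,
    )


def confusion_matrix(log: ResultLog, labels: Sequence[str]) -> pd.DataFrame:
    """Truth-by-prediction counts over records with a canonical answer.

    Rows are ground truth, columns are predictions; row sums equal the
    per-label scored task counts.
    """
    labels = list(labels)
    mat = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for rec in log.records:
        if rec.result.status != OK:
            continue
        mat.loc[rec.task.truth, rec.result.answer] += 1
    return mat


def per_label_recall(matrix: pd.DataFrame) -> tuple[dict[str, float], float]:
    """Diagonal over row sum per label, plus the macro (unweighted) average.

    Labels with no scored tasks are flagged with a warning and excluded
    from the macro average.
    """
    recalls: dict[str, float] = {}
    included: list[float] = []
    for lab in matrix.index:
        row_sum = int(matrix.loc[lab].sum())
        if row_sum == 0:
            warnings.warn(f"label {lab!r} has no scored tasks; excluded from macro")
            continue
        r = float(matrix.loc[lab, lab]) / row_sum
        recalls[lab] = r
        included.append(r)
    if not included:
        raise ValueError("no label has scored tasks")
    return recalls, float(np.mean(included))


def compare_runs(
    logs: Iterable[ResultLog],
    iterations: int = DEFAULT_BOOTSTRAP_ITERATIONS,
    seed: int = 0,
    failure_policy: str = EXCLUDE,
) -> pd.DataFrame:
    """Tidy accuracy/CI table across runs, keyed by (dataset, method, shots).

    Metadata keys ``dataset``, ``sampler`` and ``k`` identify each run.
    Runs whose task sets differ trigger a warning carrying the
    intersection size.
    """
    logs = list(logs)
    if not logs:
        raise ValueError("no runs to compare")
    task_sets = [set(r.task.task_id for r in log.records) for log in logs]
    common = set.intersection(*task_sets)
    if any(ts != common for ts in task_sets):
        warnings.warn(
            f"runs cover different task sets; intersection size {len(common)}"
        )
    rows = []
    for log in logs:
        vec = score(log, failure_policy)
        ci = bootstrap_ci(vec, iterations=iterations, seed=seed)
        rows.append(
            {
                "dataset": log.metadata.get("dataset", ""),
                "method": log.metadata.get("sampler", ""),
                "shots": log.metadata.get("k", 0),
                "n_scored": vec.n,
                "n_failed": vec.n_failed,
                "n_unmapped": vec.n_unmapped,
                "accuracy": ci.point,
                "lower_ci": ci.lower,
                "upper_ci": ci.upper,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["dataset", "method", "shots"])
        .reset_index(drop=True)
    )
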