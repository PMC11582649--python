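"""Analysis of the model's free-text reasoning ('thoughts').

The pipeline embeds each task's reasoning text, reduces the embedding
matrix to at most 200 principal components, projects to 2-D with t-SNE
(perplexity 30, seed 42 by default), and quantifies how well the projected
points cluster by the model's answers and by the ground-truth labels using
mean silhouette scores.  Increasing separation with more in-context shots
indicates that the exemplars sharpen not just the answers but the
reasoning itself.

A real run would use a hosted text-embedding service; a deterministic
hashing embedder ships here so the analysis is testable offline.
"""

from __future__ import annotations

import hashlib
import re
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_samples

from .evaluation import OK, ResultLog

_TOKEN_RE = re.compile(r"[a-z0-9]+")


class TextEmbedder(Protocol):
    """Contract: deterministic text -> vector mapping."""

    name: str
    dim: int

    def embed(self, text: str) -> np.ndarray: ...


@dataclass
class HashingTextEmbedder:
    """Seeded feature-hashing bag-of-words embedder (offline test double).

    Tokens are lowercased alphanumerics; each token hashes (with the seed
    mixed in) to a signed bucket, and the count vector is L2-normalized.
    Deterministic per (text, seed); not a semantic embedding, but texts
    sharing vocabulary land near each other, which is all the cluster
    analyses need.
    """

    dim: int = 256
    seed: int = 0
    name: str = "hashing"

    def embed(self, text: str) -> np.ndarray:
        v = np.zeros(self.dim, dtype=np.float64)
        for tok in _TOKEN_RE.findall(text.lower()):
            h = hashlib.sha256(f"{self.seed}:{tok}".encode()).digest()
            bucket = int.from_bytes(h[:4], "little") % self.dim
            sign = 1.0 if h[4] % 2 == 0 else -1.0
            v[bucket] += sign
        norm = np.linalg.norm(v)
        if norm > 0:
            v /= norm
        else:
            v[0] = 1.0  # empty-vocabulary fallback keeps vectors non-zero
        return v


@dataclass(frozen=True)
class ProjectionConfig:
    """PCA + t-SNE settings (defaults: 200 components, perplexity 30, seed 42)."""

    pca_components: int = 200
    perplexity: float = 30.0
    seed: int = 42


def embed_thoughts(
    log: ResultLog, embedder: TextEmbedder
) -> tuple[np.ndarray, list[str]]:
    """One vector per record with non-empty thoughts; excluded count logged."""
    vectors: list[np.ndarray] = []
    ids: list[str] = []
    n_excluded = 0
    for rec in log.records:
        if not rec.result.thoughts.strip():
            n_excluded += 1
            continue
        vectors.append(embedder.embed(rec.result.thoughts))
        ids.append(rec.task.task_id)
    if not vectors:
        raise ValueError("no records with non-empty thoughts")
    if n_excluded:
        warnings.warn(f"excluded {n_excluded} record(s) with empty thoughts")
    return np.vstack(vectors), ids


def project(matrix: np.ndarray, config: ProjectionConfig | None = None) -> np.ndarray:
    """PCA reduction followed by 2-D t-SNE; reproducible given the seed.

    The PCA stage is capped at min(n - 1, dim) components with a warning
    when the requested count exceeds the rank bound.  The perplexity must
    satisfy perplexity < (n - 1) / 3 or a config error with a suggested
    value is raised.
    """
    config = config or ProjectionConfig()
    matrix = np.asarray(matrix, dtype=np.float64)
    n, dim = matrix.shape
    if n < 5:
        raise ValueError("projection needs at least 5 points")
    max_perp = (n - 1) / 3
    if config.perplexity >= max_perp:
        raise ValueError(
            f"perplexity {config.perplexity} too large for n={n}; "
            f"must be < {max_perp:.1f} (try {max(1.0, max_perp - 1):.0f})"
        )
    rank_bound = min(n - 1, dim)
    components = config.pca_components
    if components > rank_bound:
        warnings.warn(
            f"pca components capped at {rank_bound} (requested {components})"
        )
        components = rank_bound
    reduced = PCA(n_components=components, random_state=config.seed).fit_transform(
        matrix
    )
    coords = TSNE(
        n_components=2,
        perplexity=config.perplexity,
        random_state=config.seed,
        init="pca",
    ).fit_transform(reduced)
    return np.asarray(coords, dtype=np.float64)


def silhouette(points: np.ndarray, labels: Sequence[str]) -> float:
    """Mean silhouette score of points under a labelling, Euclidean metric.

    For each point, a = mean distance to its own cluster, b = smallest mean
    distance to another cluster, score = (b - a) / max(a, b); singleton
    clusters score 0 by convention.  Result lies in [-1, 1].
    """
    points = np.asarray(points, dtype=np.float64)
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("silhouette needs at least 2 distinct labels")
    if len(labels) != len(points):
        raise ValueError("labels length must match point count")
    return float(np.mean(silhouette_samples(points, labels, metric="euclidean")))


def separation_report(
    logs: Sequence[ResultLog],
    embedder: TextEmbedder,
    config: ProjectionConfig | None = None,
) -> pd.DataFrame:
    """Silhouettes of projected reasoning per run, against answers and labels.

    Runs with no parsed answers (or a single distinct cluster) are filtered
    out.  Returns a tidy table with one row per run: shots, n, S_answers,
    S_labels.
    """
    rows = []
    for log in logs:
        parsed = [r for r in log.records if r.result.status == OK
                  and r.result.thoughts.strip()]
        if not parsed:
            continue
        sub = ResultLog(records=parsed, metadata=log.metadata)
        matrix, _ = embed_thoughts(sub, embedder)
        coords = project(matrix, config)
        answers = [r.result.answer for r in parsed]
        truths = [r.task.truth for r in parsed]
        row = {
            "dataset": log.metadata.get("dataset", ""),
            "shots": log.metadata.get("k", 0),
            "n": len(parsed),
        }
        row["S_answers"] = (
            silhouette(coords, answers) if len(set(answers)) >= 2 else np.nan
        )
        row["S_labels"] = (
            silhouette(coords, truths) if len(set(truths)) >= 2 else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)


def term_frequencies(log: ResultLog, by: str = "answer", top: int = 20) -> pd.DataFrame:
    """Per-label token counts over reasoning texts (word-cloud stand-in)."""
    if by not in ("answer", "truth"):
        raise ValueError("by must be 'answer' or 'truth'")
    counters: dict[str, Counter] = {}
    for rec in log.records:
        key = rec.result.answer if by == "answer" else rec.task.truth
        if key is None:
            continue
        counters.setdefault(key, Counter()).update(
            _TOKEN_RE.findall(rec.result.thoughts.lower())
        )
    rows = []
    for key, counter in sorted(counters.items()):
        for term, count in counter.most_common(top):
            rows.append({"label": key, "term": term, "count": count})
    return pd.DataFrame(rows)


def plot_projection(
    coords: np.ndarray,
    labels: Sequence[str],
    path: str,
    title: str = "",
) -> None:
    """Scatter plot of projected reasoning coordinates, colored by label."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    labels = np.asarray(labels)
    for lab in sorted(set(labels.tolist())):
        mask = labels == lab
        ax.scatter(coords[mask, 0], coords[mask, 1], s=12, label=lab, alpha=0.8)
    ax.legend(fontsize=7)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
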