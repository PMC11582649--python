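"""Embedding-space comparators: cosine nearest neighbour and a linear probe.

These play the role of the classical baselines against which in-context
learning is judged: assigning a query the label of its most cosine-similar
training embedding, or training a single linear layer (softmax regression)
on frozen feature vectors.  The probe trains with the Adam optimizer at
learning rate 0.001 under a cross-entropy loss for a small number of
epochs (1, 3, 5 or 10 are the conventional settings), full-batch whenever
the training set is at most 256 tiles so small runs are deterministic.

The matched-conditions protocol trains one probe per evaluation task on
exactly the tiles of that task's few-shot context, mirroring a comparison
in which the in-context examples and the training set are identical.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .data_model import EmbeddingIndex
from .sampler import FewShotContext


@dataclass
class ProbeConfig:
    learning_rate: float = 0.001
    epochs: int = 10
    seed: int = 0
    standardize: bool = True
    full_batch_limit: int = 256
    batch_size: int = 32  # used only above full_batch_limit
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8


def nn_classify(
    train_index: EmbeddingIndex, query: np.ndarray, k: int = 1
) -> str:
    """Label of the most cosine-similar training tile (majority for k > 1).

    Majority ties are broken by summed similarity of each label's
    supporters, then by the smallest supporting tile_id.
    """
    if len(train_index) == 0:
        raise ValueError("training index is empty")
    if train_index.labels is None:
        raise ValueError("training index carries no labels")
    query = np.asarray(query, dtype=np.float64).ravel()
    if query.shape[0] != train_index.dim:
        raise ValueError(
            f"query dim {query.shape[0]} != index dim {train_index.dim}"
        )
    qn = np.linalg.norm(query)
    if qn == 0:
        raise ValueError("zero query vector")
    m = train_index.matrix.astype(np.float64)
    sims = m @ query / (np.linalg.norm(m, axis=1) * qn)
    order = sorted(
        range(len(train_index)),
        key=lambda i: (-sims[i], train_index.tile_ids[i]),
    )
    top = order[: min(k, len(order))]
    votes = Counter(train_index.labels[i] for i in top)
    best = max(
        votes,
        key=lambda lab: (
            votes[lab],
            sum(sims[i] for i in top if train_index.labels[i] == lab),
            # final tie-break: smallest supporting tile_id wins -> negate sort
            min(train_index.tile_ids[i] for i in top if train_index.labels[i] == lab),
        ),
    )
    # the tile_id component above prefers the *largest* id under max();
    # resolve exact remaining ties explicitly by smallest supporter id
    contenders = [
        lab
        for lab in votes
        if votes[lab] == votes[best]
        and np.isclose(
            sum(sims[i] for i in top if train_index.labels[i] == lab),
            sum(sims[i] for i in top if train_index.labels[i] == best),
        )
    ]
    if len(contenders) > 1:
        best = min(
            contenders,
            key=lambda lab: min(
                train_index.tile_ids[i]
                for i in top
                if train_index.labels[i] == lab
            ),
        )
    return best


@dataclass
class LinearProbe:
    """A single linear layer over frozen embeddings with softmax output."""

    weights: np.ndarray  # (dim, n_classes)
    bias: np.ndarray  # (n_classes,)
    classes: tuple[str, ...]
    config: ProbeConfig
    loss_trajectory: list[float] = field(default_factory=list)
    feature_mean: np.ndarray | None = None
    feature_std: np.ndarray | None = None

    def _prepare(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        single = x.ndim == 1
        if single:
            x = x[None, :]
        if x.shape[1] != self.weights.shape[0]:
            raise ValueError(
                f"input dim {x.shape[1]} != probe dim {self.weights.shape[0]}"
            )
        if self.feature_mean is not None:
            x = (x - self.feature_mean) / self.feature_std
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = self._prepare(x)
        logits = x @ self.weights + self.bias
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        return p

    def predict(self, x: np.ndarray) -> str | list[str]:
        p = self.predict_proba(np.asarray(x))
        idx = p.argmax(axis=1)
        out = [self.classes[i] for i in idx]
        return out[0] if np.asarray(x).ndim == 1 else out

    def to_json(self) -> dict:
        return {
            "classes": list(self.classes),
            "weights": self.weights.tolist(),
            "bias": self.bias.tolist(),
            "feature_mean": None if self.feature_mean is None else self.feature_mean.tolist(),
            "feature_std": None if self.feature_std is None else self.feature_std.tolist(),
            "config": vars(self.config),
            "loss_trajectory": self.loss_trajectory,
        }

    @classmethod
    def from_json(cls, d: dict) -> "LinearProbe":
        probe = cls(
            weights=np.array(d["weights"]),
            bias=np.array(d["bias"]),
            classes=tuple(d["classes"]),
            config=ProbeConfig(**d["config"]),
            loss_trajectory=list(d["loss_trajectory"]),
        )
        if d.get("feature_mean") is not None:
            probe.feature_mean = np.array(d["feature_mean"])
            probe.feature_std = np.array(d["feature_std"])
        return probe


def _cross_entropy(p: np.ndarray, y: np.ndarray) -> float:
    return float(-np.log(np.clip(p[np.arange(len(y)), y], 1e-12, None)).mean())


def train_probe(
    train_index: EmbeddingIndex,
    config: ProbeConfig | None = None,
) -> LinearProbe:
    """Fit the linear probe on an embedding index with labels.

    Weight initialization is seeded uniform in +-1/sqrt(dim).  Runs
    full-batch (one gradient step per epoch) up to ``full_batch_limit``
    tiles, which makes small in-context training sets deterministic;
    larger sets use seeded mini-batch shuffling.  Epoch-end cross-entropy
    on the full training set is recorded as the loss trajectory;
    ``epochs=0`` returns the probe at initialization.
    """
    config = config or ProbeConfig()
    if train_index.labels is None:
        raise ValueError("training index carries no labels")
    classes = tuple(sorted(set(train_index.labels)))
    if len(classes) < 2:
        raise ValueError("probe training needs at least 2 classes")
    class_row = {c: i for i, c in enumerate(classes)}
    x = train_index.matrix.astype(np.float64)
    y = np.array([class_row[lab] for lab in train_index.labels])
    dim, n_classes = x.shape[1], len(classes)

    mean = std = None
    if config.standardize:
        mean = x.mean(axis=0)
        std = x.std(axis=0)
        std = np.where(std < 1e-12, 1.0, std)
        x = (x - mean) / std

    rng = np.random.default_rng(config.seed)
    scale = 1.0 / np.sqrt(dim)
    w = rng.uniform(-scale, scale, size=(dim, n_classes))
    b = np.zeros(n_classes)

    m_w = np.zeros_like(w); v_w = np.zeros_like(w)
    m_b = np.zeros_like(b); v_b = np.zeros_like(b)
    t = 0
    losses: list[float] = []

    def forward(xb):
        logits = xb @ w + b
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        return p

    full_batch = len(x) <= config.full_batch_limit
    for _ in range(config.epochs):
        if full_batch:
            batches = [np.arange(len(x))]
        else:
            order = rng.permutation(len(x))
            batches = [
                order[i : i + config.batch_size]
                for i in range(0, len(order), config.batch_size)
            ]
        for idx in batches:
            xb, yb = x[idx], y[idx]
            p = forward(xb)
            grad_logits = p.copy()
            grad_logits[np.arange(len(yb)), yb] -= 1.0
            grad_logits /= len(yb)
            g_w = xb.T @ grad_logits
            g_b = grad_logits.sum(axis=0)
            t += 1
            for g, mom, vel, param in (
                (g_w, m_w, v_w, w),
                (g_b, m_b, v_b, b),
            ):
                mom *= config.beta1
                mom += (1 - config.beta1) * g
                vel *= config.beta2
                vel += (1 - config.beta2) * g * g
                m_hat = mom / (1 - config.beta1**t)
                v_hat = vel / (1 - config.beta2**t)
                param -= config.learning_rate * m_hat / (np.sqrt(v_hat) + config.eps)
        losses.append(_cross_entropy(forward(x), y))

    probe = LinearProbe(
        weights=w,
        bias=b,
        classes=classes,
        config=config,
        loss_trajectory=losses,
        feature_mean=mean,
        feature_std=std,
    )
    return probe


def probe_predict(probe: LinearProbe, query: np.ndarray) -> tuple[str, dict[str, float]]:
    """Argmax label and the full class-probability map for one query."""
    query = np.asarray(query, dtype=np.float64).ravel()
    p = probe.predict_proba(query)[0]
    label = probe.classes[int(p.argmax())]
    return label, {c: float(pi) for c, pi in zip(probe.classes, p)}


def train_probe_on_context(
    index: EmbeddingIndex,
    context: FewShotContext,
    config: ProbeConfig | None = None,
) -> LinearProbe:
    """Matched-conditions probe: the training set is exactly the context tiles."""
    sub = index.subset(context.tile_ids())
    # labels come from the context (they were assigned at sampling time)
    sub.labels = [ex.label for ex in context.exemplars]
    return train_probe(sub, config)
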