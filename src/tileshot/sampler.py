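"""Few-shot exemplar selection: kNN retrieval and random sampling.

For each classification task, ``k`` exemplar tiles are selected *per label*
(so a context holds k * n_labels exemplars in total).  kNN retrieval picks,
within each label, the k tiles whose embeddings are most cosine-similar to
the target; random sampling draws uniformly.  Both honour two exclusion
rules: the target tile itself is never a candidate, and (optionally) no
exemplar may come from the same patient as the target, which prevents the
model from keying on patient-specific tissue morphology rather than the
class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import EmbeddingIndex, Manifest

KNN = "knn"
RANDOM = "random"


class SamplingError(ValueError):
    """Raised when a label has too few eligible exemplar candidates."""


@dataclass(frozen=True)
class Exemplar:
    tile_id: str
    label: str
    similarity: float | None  # None for random sampling


@dataclass
class FewShotContext:
    """The ordered exemplar set for one task.

    ``exemplars`` is label-major: all k exemplars for the first label (most
    similar first for kNN), then the next label, and so on in LabelSet
    order.  Prompt assembly re-interleaves them into rounds.
    """

    target_tile_id: str
    method: str
    k: int
    label_order: tuple[str, ...]
    exemplars: list[Exemplar] = field(default_factory=list)

    def per_label(self) -> dict[str, list[Exemplar]]:
        out: dict[str, list[Exemplar]] = {lab: [] for lab in self.label_order}
        for ex in self.exemplars:
            out.setdefault(ex.label, []).append(ex)
        return out

    def tile_ids(self) -> list[str]:
        return [ex.tile_id for ex in self.exemplars]

    def rounds(self) -> list[list[Exemplar]]:
        """Round r holds the r-th best exemplar of every label, label order."""
        by_label = self.per_label()
        return [
            [by_label[lab][r] for lab in self.label_order if r < len(by_label[lab])]
            for r in range(self.k)
        ]

    def to_json_record(self) -> dict:
        return {
            "target": self.target_tile_id,
            "method": self.method,
            "k": self.k,
            "exemplars": [
                {"tile_id": e.tile_id, "label": e.label, "sim": e.similarity}
                for e in self.exemplars
            ],
        }


def _eligible(
    index: EmbeddingIndex,
    target: str,
    label: str,
    exclude_same_patient: bool,
) -> list[int]:
    """Candidate rows of ``label``, excluding target and same-patient tiles.

    A pair counts as same-patient only when both patient ids are present;
    missing ids are treated as distinct patients.
    """
    t_row = index.row_of(target)
    t_patient = index.patient_of(target)
    rows = []
    for i, tid in enumerate(index.tile_ids):
        if i == t_row or index.labels[i] != label:
            continue
        if exclude_same_patient and t_patient is not None:
            p = None if index.patient_ids is None else index.patient_ids[i]
            if p is not None and p == t_patient:
                continue
        rows.append(i)
    return rows


def knn_sample(
    index: EmbeddingIndex,
    target: str,
    k: int,
    label_order: tuple[str, ...] | list[str],
    exclude_same_patient: bool = True,
) -> FewShotContext:
    """Select, per label, the k most cosine-similar eligible tiles.

    Within each label the exemplars are ordered most-similar-first (that is
    the order in which they will be shown to the model).  Ties in similarity
    are broken by ascending tile_id.  Selecting the top-k independently is
    equivalent to maximising the sum of similarities over k-subsets, since
    the summands are independent.
    """
    if index.labels is None:
        raise ValueError("index carries no labels")
    if k < 1:
        raise ValueError("k must be >= 1")
    sims = index.similarities_to(target)
    context = FewShotContext(
        target_tile_id=target, method=KNN, k=k, label_order=tuple(label_order)
    )
    for label in context.label_order:
        rows = _eligible(index, target, label, exclude_same_patient)
        if len(rows) < k:
            raise SamplingError(
                f"label {label!r}: need {k} candidates, only {len(rows)} "
                f"eligible (shortfall {k - len(rows)})"
            )
        rows.sort(key=lambda i: (-sims[i], index.tile_ids[i]))
        for i in rows[:k]:
            context.exemplars.append(
                Exemplar(index.tile_ids[i], label, float(sims[i]))
            )
    return context


def random_sample(
    index: EmbeddingIndex,
    target: str,
    k: int,
    label_order: tuple[str, ...] | list[str],
    seed: int,
    exclude_same_patient: bool = True,
) -> FewShotContext:
    """Draw k exemplars per label uniformly without replacement, seeded.

    Applies the same target/patient exclusions as kNN sampling so the two
    arms differ only in how exemplars are chosen.  Similarity fields are
    null.
    """
    if index.labels is None:
        raise ValueError("index carries no labels")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    context = FewShotContext(
        target_tile_id=target, method=RANDOM, k=k, label_order=tuple(label_order)
    )
    for label in context.label_order:
        rows = _eligible(index, target, label, exclude_same_patient)
        if len(rows) < k:
            raise SamplingError(
                f"label {label!r}: need {k} candidates, only {len(rows)} "
                f"eligible (shortfall {k - len(rows)})"
            )
        chosen = rng.choice(len(rows), size=k, replace=False)
        for j in chosen:
            context.exemplars.append(Exemplar(index.tile_ids[rows[j]], label, None))
    return context


def verify_context(
    context: FewShotContext,
    index: EmbeddingIndex,
    target: str | None = None,
    exclude_same_patient: bool = True,
) -> list[str]:
    """Re-check all FewShotContext invariants; return violation messages.

    Used by tests and after deserialization; an empty list means valid.
    """
    violations: list[str] = []
    target = target or context.target_tile_id
    if target != context.target_tile_id:
        violations.append("target mismatch")
    by_label = context.per_label()
    for label in context.label_order:
        got = by_label.get(label, [])
        if len(got) != context.k:
            violations.append(
                f"label {label!r}: {len(got)} exemplars, expected {context.k}"
            )
    for ex in context.exemplars:
        if ex.tile_id == target:
            violations.append("target leakage")
        if ex.label not in context.label_order:
            violations.append(f"exemplar label {ex.label!r} outside label set")
    t_patient = index.patient_of(target) if target in index._row else None
    if exclude_same_patient and t_patient is not None:
        for ex in context.exemplars:
            if index.patient_of(ex.tile_id) == t_patient:
                violations.append(
                    f"patient overlap: exemplar {ex.tile_id!r} shares "
                    f"patient {t_patient!r} with target"
                )
    if context.method == KNN:
        for label, exs in by_label.items():
            sims = [e.similarity for e in exs]
            if any(s is None for s in sims):
                violations.append(f"label {label!r}: missing similarity")
            elif any(sims[i] < sims[i + 1] for i in range(len(sims) - 1)):
                violations.append(f"label {label!r}: ordering")
    return violations
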