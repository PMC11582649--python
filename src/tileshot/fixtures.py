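"""Seeded synthetic manifests, embeddings, and toy tile images.

The generator emulates the statistical shape that tile classification over
foundation-model embeddings assumes: classes form clusters in embedding
space, tiles from the same patient huddle closer together than tiles from
different patients of the same class, and the test split is balanced
across labels.  Class centers sit on a seeded random orthogonal frame
scaled by the separation ``delta``; each tile adds a per-patient offset
(scale ``sigma``/2) and independent tile noise (scale ``sigma``).  Images
are decorative class-hued noise textures — encoders are never run on them;
the generated matrix plays the role of pre-computed encoder output.

Everything is a pure function of (spec, seed): the same spec reproduces
byte-identical embeddings and images.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .data_model import (
    EmbeddingIndex,
    EvaluationTask,
    LabelSet,
    Manifest,
    TileRecord,
    write_manifest,
    write_embeddings,
)
from .evaluation import OutcomeVector


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic tile population.

    Defaults give two well-separated classes (delta/sigma = 8) in the
    768-dimensional space typical of ViT-B-style encoders, with ten
    patients per class contributing ten tiles each — enough patient
    structure for the same-patient exclusion rule to matter.
    """

    classes: tuple[str, ...] = ("TUM", "NORM")
    dim: int = 768
    delta: float = 8.0  # class-center separation
    sigma: float = 1.0  # within-class tile noise scale
    patients_per_class: int = 10
    tiles_per_patient: int = 10
    seed: int = 0
    image_px: int = 32

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if min(self.patients_per_class, self.tiles_per_patient, self.image_px) < 1:
            raise ValueError("all counts must be >= 1")

    @property
    def label_set(self) -> LabelSet:
        return LabelSet(tuple(self.classes))


def _orthogonal_frame(rng: np.random.Generator, dim: int, g: int) -> np.ndarray:
    """g orthonormal directions in R^dim via QR of a Gaussian matrix."""
    a = rng.standard_normal((dim, g))
    q, r = np.linalg.qr(a)
    # fix signs so the frame is a deterministic function of the draw
    return q * np.sign(np.diag(r))


def _class_hue(rng: np.random.Generator) -> tuple[int, int, int]:
    return tuple(int(c) for c in rng.integers(60, 220, size=3))


def _noise_png(rng: np.random.Generator, px: int, hue: tuple[int, int, int]) -> bytes:
    base = rng.integers(-40, 40, size=(px, px, 3))
    img = np.clip(np.array(hue)[None, None, :] + base, 0, 255).astype(np.uint8)
    buf = io.BytesIO()
    Image.fromarray(img, "RGB").save(buf, format="PNG")
    return buf.getvalue()


def generate(
    spec: FixtureSpec, out_dir: str | Path | None = None
) -> tuple[Manifest, EmbeddingIndex]:
    """Build a manifest + embedding index (and PNG tiles when out_dir given).

    Tile ids are ``{label}-p{patient:02d}-t{tile:03d}``; patient ids are
    shared across a patient's tiles so leakage rules can be exercised.
    When ``out_dir`` is given, the manifest, embeddings, per-tile PNGs and
    a ``fixture.json`` recording the spec are written there.
    """
    rng = np.random.default_rng(spec.seed)
    g = len(spec.classes)
    frame = _orthogonal_frame(rng, spec.dim, g)
    centers = frame.T * spec.delta  # (g, dim)

    records: list[TileRecord] = []
    vectors: list[np.ndarray] = []
    images: dict[str, bytes] = {}
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        (out_dir / "tiles").mkdir(parents=True, exist_ok=True)

    for ci, label in enumerate(spec.classes):
        hue = _class_hue(rng)
        for p in range(spec.patients_per_class):
            patient_id = f"{label}-patient{p:02d}"
            offset = rng.standard_normal(spec.dim) * (spec.sigma / 2)
            for t in range(spec.tiles_per_patient):
                tile_id = f"{label}-p{p:02d}-t{t:03d}"
                vec = (
                    centers[ci]
                    + offset
                    + rng.standard_normal(spec.dim) * spec.sigma
                )
                vectors.append(vec.astype(np.float32))
                image_path = None
                if out_dir is not None:
                    png = _noise_png(rng, spec.image_px, hue)
                    image_path = str(out_dir / "tiles" / f"{tile_id}.png")
                    Path(image_path).write_bytes(png)
                    images[tile_id] = png
                records.append(
                    TileRecord(
                        tile_id=tile_id,
                        label=label,
                        patient_id=patient_id,
                        image_path=image_path,
                        agreement=True,
                    )
                )

    manifest = Manifest(records, spec.label_set)
    index = EmbeddingIndex.from_manifest(manifest, np.vstack(vectors))
    if out_dir is not None:
        write_manifest(manifest, out_dir / "manifest.tsv")
        write_embeddings(index, out_dir / "embeddings")
        (out_dir / "fixture.json").write_text(
            json.dumps(asdict(spec), indent=1, default=list)
        )
    return manifest, index


def balanced_test_split(
    manifest: Manifest, per_class: int, seed: int
) -> list[EvaluationTask]:
    """Draw a balanced task list: ``per_class`` seeded draws per label.

    Sampling is without replacement within each label; the remaining tiles
    implicitly form the exemplar retrieval pool (the sampler excludes the
    target itself at query time).  Typical sizes are 30 per class for a
    binary task (60 tasks) and 15 per class for an 8-class task (120).
    """
    if per_class < 1:
        raise ValueError("per_class must be >= 1")
    rng = np.random.default_rng(seed)
    tasks: list[EvaluationTask] = []
    for label in manifest.label_set:
        pool = [r for r in manifest if r.label == label]
        if len(pool) < per_class:
            raise ValueError(
                f"class {label!r} has {len(pool)} tiles, need {per_class}"
            )
        chosen = rng.choice(len(pool), size=per_class, replace=False)
        for j in sorted(chosen):
            rec = pool[j]
            tasks.append(
                EvaluationTask(
                    task_id=f"task-{rec.tile_id}",
                    target_tile_id=rec.tile_id,
                    truth=label,
                )
            )
    return tasks


def outcome_fixture(n_correct: int, n_total: int) -> OutcomeVector:
    """Deterministic binary vector with the given success count.

    The bootstrap is invariant to ordering, so the vector is simply
    ``n_correct`` ones followed by zeros.  Used to feed the evaluation
    machinery from printed accuracy/denominator pairs.
    """
    if not 0 <= n_correct <= n_total:
        raise ValueError(f"need 0 <= n_correct <= n_total, got {n_correct}/{n_total}")
    values = np.concatenate(
        [np.ones(n_correct, dtype=np.int8), np.zeros(n_total - n_correct, dtype=np.int8)]
    )
    return OutcomeVector(values, labels=[""] * n_total)


def error_schedule(
    k: int, eps_zero: float = 0.4, eps_max: float = 0.0, max_shots: int = 10
) -> float:
    """Mock error rate decreasing strictly in the shot count k.

    Linear interpolation from ``eps_zero`` at k = 0 to ``eps_max`` at
    ``max_shots``; endpoints are honored exactly.  Feeding this schedule
    to the mock backend makes expected accuracy increase with k, so the
    evaluation pipeline's ability to surface a monotone trend can be
    asserted without any hosted model.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if not 0 <= eps_max < eps_zero <= 1:
        raise ValueError("need 0 <= eps_max < eps_zero <= 1")
    frac = min(k, max_shots) / max_shots
    return eps_zero + (eps_max - eps_zero) * frac
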