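"""Domain types and I/O for tile manifests and embedding matrices.

A *tile* is a small fixed-size crop of a whole-slide histology image.  Each
tile carries a class label (e.g. tissue type), optionally the patient it came
from, a path to its PNG rendering, and optionally an annotator-agreement flag.
Embeddings are dense feature vectors (default length 768, the output size of
ViT-B-style histopathology encoders) aligned row-for-row with the manifest.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ["tile_id", "label", "patient_id", "image_path", "agreement"]
DEFAULT_EMBEDDING_DIM = 768


class ManifestFormatError(ValueError):
    """Raised when a manifest file is structurally invalid."""


class ManifestValidationError(ValueError):
    """Raised when manifest contents violate label/uniqueness rules."""


@dataclass(frozen=True)
class LabelSet:
    """Ordered canonical class symbols with alias resolution and exclusions.

    ``labels`` fixes both membership and the order in which labels are
    enumerated in prompts and cycled through during exemplar sampling.
    ``aliases`` maps free-text answer strings (case-insensitive) to canonical
    symbols; identity entries are implicit.  ``excluded`` labels (e.g. a
    background class) are dropped at manifest load and never appear in tasks.
    """

    labels: tuple[str, ...]
    aliases: Mapping[str, str] = field(default_factory=dict)
    excluded: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("canonical labels must be unique")
        for alias, target in self.aliases.items():
            if target not in self.labels:
                raise ValueError(
                    f"alias {alias!r} maps to unknown label {target!r}"
                )
        lowered: dict[str, str] = {}
        for alias, target in self.aliases.items():
            key = alias.strip().lower()
            if key in lowered and lowered[key] != target:
                raise ValueError(
                    f"alias {alias!r} maps to both {lowered[key]!r} and {target!r}"
                )
            lowered[key] = target

    @classmethod
    def from_config(
        cls,
        labels: Sequence[str],
        aliases: Mapping[str, str] | None = None,
        excluded: Sequence[str] = (),
    ) -> "LabelSet":
        return cls(tuple(labels), dict(aliases or {}), tuple(excluded))

    def alias_map(self) -> dict[str, str]:
        """Total lowercase alias map, identity entries included."""
        m = {lab.lower(): lab for lab in self.labels}
        for alias, target in self.aliases.items():
            key = alias.strip().lower()
            if key in m and m[key] != target:
                raise ValueError(
                    f"alias {alias!r} collides with existing mapping to {m[key]!r}"
                )
            m[key] = target
        return m

    def canonicalize(self, text: str) -> str | None:
        """Resolve a free-text label to its canonical symbol, or None."""
        return self.alias_map().get(text.strip().lower())

    def __contains__(self, label: object) -> bool:
        return label in self.labels

    def __iter__(self):
        return iter(self.labels)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class TileRecord:
    """One catalogue entry: identity, class label, provenance, assets."""

    tile_id: str
    label: str
    patient_id: str | None = None
    image_path: str | None = None
    agreement: bool | None = None


@dataclass(frozen=True)
class EvaluationTask:
    """A single classification query: which tile, and the expected answer."""

    task_id: str
    target_tile_id: str
    truth: str


@dataclass
class Manifest:
    """An ordered collection of TileRecord with a shared LabelSet."""

    records: list[TileRecord]
    label_set: LabelSet

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.tile_id in seen:
                raise ManifestValidationError(
                    f"duplicate tile_id {rec.tile_id!r}"
                )
            seen.add(rec.tile_id)
            if rec.label not in self.label_set:
                raise ManifestValidationError(
                    f"tile {rec.tile_id!r} has unknown label {rec.label!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def tile_ids(self) -> list[str]:
        return [r.tile_id for r in self.records]

    def by_id(self, tile_id: str) -> TileRecord:
        try:
            return self._index()[tile_id]
        except KeyError:
            raise KeyError(f"tile {tile_id!r} not in manifest") from None

    def _index(self) -> dict[str, TileRecord]:
        if not hasattr(self, "_idx") or len(self._idx) != len(self.records):
            self._idx = {r.tile_id: r for r in self.records}
        return self._idx

    def labels_of(self, tile_ids: Iterable[str]) -> list[str]:
        return [self.by_id(t).label for t in tile_ids]


def read_manifest(path: str | Path, label_set: LabelSet) -> Manifest:
    """Read a TSV manifest, validating labels and dropping excluded classes.

    The file must carry a header with at least ``tile_id`` and ``label``;
    the optional columns are ``patient_id``, ``image_path``, ``agreement``
    (values ``yes``/``no``, empty = unknown).  Rows whose label is on the
    LabelSet's excluded list are dropped with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("tile_id", "label"):
        if col not in df.columns:
            raise ManifestFormatError(f"manifest missing required column {col!r}")
    dupes = df["tile_id"][df["tile_id"].duplicated()].tolist()
    if dupes:
        raise ManifestValidationError(f"duplicate tile_id(s): {sorted(set(dupes))}")

    n_before = len(df)
    if label_set.excluded:
        df = df[~df["label"].isin(label_set.excluded)]
        n_dropped = n_before - len(df)
        if n_dropped:
            logger.info(
                "dropped %d record(s) with excluded label(s) %s",
                n_dropped,
                list(label_set.excluded),
            )

    unknown = sorted(set(df["label"]) - set(label_set.labels))
    if unknown:
        raise ManifestValidationError(f"unknown label(s) in manifest: {unknown}")

    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        agreement_raw = d.get("agreement", "")
        agreement = {"yes": True, "no": False, "": None}.get(agreement_raw)
        if agreement is None and agreement_raw not in ("", "yes", "no"):
            raise ManifestFormatError(
                f"agreement value {agreement_raw!r} for tile {d['tile_id']!r} "
                "must be 'yes', 'no' or empty"
            )
        records.append(
            TileRecord(
                tile_id=d["tile_id"],
                label=d["label"],
                patient_id=d.get("patient_id") or None,
                image_path=d.get("image_path") or None,
                agreement=agreement,
            )
        )
    return Manifest(records, label_set)


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    rows = []
    for r in manifest:
        rows.append(
            {
                "tile_id": r.tile_id,
                "label": r.label,
                "patient_id": r.patient_id or "",
                "image_path": r.image_path or "",
                "agreement": {True: "yes", False: "no", None: ""}[r.agreement],
            }
        )
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


def filter_unanimous(manifest: Manifest) -> Manifest:
    """Keep only tiles whose annotators reached unanimous consensus.

    Mirrors the common practice of restricting test sets to unambiguous
    cases when labels come from a panel of experts.  Every record must
    carry an agreement flag.
    """
    missing = [r.tile_id for r in manifest if r.agreement is None]
    if missing:
        raise ManifestValidationError(
            f"agreement flag missing on {len(missing)} record(s), e.g. {missing[:3]}"
        )
    kept = [r for r in manifest if r.agreement]
    if not kept:
        warnings.warn("no records with unanimous consensus; manifest is empty")
    return Manifest(kept, manifest.label_set)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity a.b / (|a||b|), in [-1, 1].

    Scale-invariant and symmetric; zero vectors are rejected because the
    similarity is undefined for them.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


class ImageEncoder(Protocol):
    """Contract for an image -> embedding function.

    Implementations must be deterministic: identical image bytes produce
    identical vectors.  No neural encoder ships with this package; the
    synthetic fixture generator plays the role of a pre-computed encoder.
    """

    name: str
    dim: int

    def encode(self, png_bytes: bytes) -> np.ndarray: ...


@dataclass
class EmbeddingIndex:
    """Tile-aligned dense matrix supporting cosine-similarity queries.

    Rows follow manifest order.  Vectors are stored unnormalized; cosine
    similarity normalizes internally, so whether an encoder L2-normalized
    its outputs is irrelevant for retrieval.
    """

    tile_ids: list[str]
    matrix: np.ndarray
    labels: list[str] | None = None
    patient_ids: list[str | None] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float32)
        if self.matrix.ndim != 2:
            raise ValueError("embedding matrix must be 2-D")
        if len(self.tile_ids) != self.matrix.shape[0]:
            raise ValueError(
                f"{len(self.tile_ids)} tile ids vs {self.matrix.shape[0]} rows"
            )
        if len(set(self.tile_ids)) != len(self.tile_ids):
            raise ValueError("tile_ids must be unique")
        if self.matrix.shape[0] and not np.all(
            np.linalg.norm(self.matrix, axis=1) > 0
        ):
            raise ValueError("all-zero embedding vectors are not admitted")
        for name, aux in (("labels", self.labels), ("patient_ids", self.patient_ids)):
            if aux is not None and len(aux) != len(self.tile_ids):
                raise ValueError(f"{name} length does not match tile count")
        self._row = {t: i for i, t in enumerate(self.tile_ids)}

    @classmethod
    def from_manifest(cls, manifest: Manifest, matrix: np.ndarray) -> "EmbeddingIndex":
        matrix = np.asarray(matrix)
        if matrix.shape[0] != len(manifest):
            raise ValueError(
                f"matrix has {matrix.shape[0]} rows but manifest has "
                f"{len(manifest)} records"
            )
        return cls(
            tile_ids=list(manifest.tile_ids),
            matrix=matrix,
            labels=[r.label for r in manifest],
            patient_ids=[r.patient_id for r in manifest],
        )

    def __len__(self) -> int:
        return len(self.tile_ids)

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def row_of(self, tile_id: str) -> int:
        try:
            return self._row[tile_id]
        except KeyError:
            raise KeyError(f"tile {tile_id!r} not in embedding index") from None

    def vector(self, tile_id: str) -> np.ndarray:
        return self.matrix[self.row_of(tile_id)]

    def label_of(self, tile_id: str) -> str:
        if self.labels is None:
            raise ValueError("index carries no labels")
        return self.labels[self.row_of(tile_id)]

    def patient_of(self, tile_id: str) -> str | None:
        if self.patient_ids is None:
            return None
        return self.patient_ids[self.row_of(tile_id)]

    def similarities_to(self, tile_id: str) -> np.ndarray:
        """Cosine similarity of every row to the given tile (float64)."""
        q = self.matrix[self.row_of(tile_id)].astype(np.float64)
        m = self.matrix.astype(np.float64)
        norms = np.linalg.norm(m, axis=1)
        return np.clip(m @ q / (norms * np.linalg.norm(q)), -1.0, 1.0)

    def subset(self, tile_ids: Sequence[str]) -> "EmbeddingIndex":
        rows = [self.row_of(t) for t in tile_ids]
        return EmbeddingIndex(
            tile_ids=list(tile_ids),
            matrix=self.matrix[rows],
            labels=None if self.labels is None else [self.labels[i] for i in rows],
            patient_ids=(
                None
                if self.patient_ids is None
                else [self.patient_ids[i] for i in rows]
            ),
        )


def neighborhood_composition(
    index: EmbeddingIndex, target: str, n: int
) -> dict[str, float]:
    """Label fractions among the n most cosine-similar tiles to ``target``.

    The target itself is excluded; ties are broken by ascending tile_id.
    Fractions sum to 1.  Used to characterise what the embedding space
    thinks a tile's neighbourhood looks like (e.g. the top-500 composition
    around a disputed tile).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > len(index) - 1:
        raise ValueError(f"n={n} exceeds index size minus target ({len(index) - 1})")
    if index.labels is None:
        raise ValueError("index carries no labels")
    sims = index.similarities_to(target)
    t_row = index.row_of(target)
    order = sorted(
        (i for i in range(len(index)) if i != t_row),
        key=lambda i: (-sims[i], index.tile_ids[i]),
    )
    top = order[:n]
    counts: dict[str, int] = {}
    for i in top:
        counts[index.labels[i]] = counts.get(index.labels[i], 0) + 1
    return {lab: c / n for lab, c in sorted(counts.items())}


def write_embeddings(index: EmbeddingIndex, path: str | Path) -> None:
    """Write an index as raw little-endian float32 plus TSV/JSON sidecars.

    ``<path>.mat`` holds the row-major matrix, ``<path>.ids.tsv`` the tile
    ids (and labels/patients when present), ``<path>.json`` the shape.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    index.matrix.astype("<f4").tofile(path.with_suffix(".mat"))
    sidecar = {
        "n_tiles": int(index.matrix.shape[0]),
        "dim": int(index.matrix.shape[1]),
        "dtype": "<f4",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    df = pd.DataFrame({"tile_id": index.tile_ids})
    if index.labels is not None:
        df["label"] = index.labels
    if index.patient_ids is not None:
        df["patient_id"] = [p or "" for p in index.patient_ids]
    df.to_csv(path.with_suffix(".ids.tsv"), sep="\t", index=False)


def read_embeddings(
    path: str | Path, manifest: Manifest | None = None
) -> EmbeddingIndex:
    """Load an index written by :func:`write_embeddings`.

    When a manifest is supplied, row count and tile id order must match it.
    """
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    n, d = sidecar["n_tiles"], sidecar["dim"]
    flat = np.fromfile(path.with_suffix(".mat"), dtype="<f4")
    if flat.size != n * d:
        raise ValueError(
            f"matrix file holds {flat.size} floats, sidecar says {n}x{d}"
        )
    matrix = flat.reshape(n, d)
    df = pd.read_csv(path.with_suffix(".ids.tsv"), sep="\t", dtype=str,
                     keep_default_na=False)
    tile_ids = df["tile_id"].tolist() if n else []
    labels = df["label"].tolist() if "label" in df.columns and n else None
    patients = (
        [p or None for p in df["patient_id"]]
        if "patient_id" in df.columns and n
        else None
    )
    if manifest is not None:
        if len(manifest) != n:
            raise ValueError(
                f"embedding rows ({n}) do not match manifest ({len(manifest)})"
            )
        if manifest.tile_ids != tile_ids:
            raise ValueError("tile id order differs between manifest and embeddings")
    return EmbeddingIndex(tile_ids, matrix, labels, patients)
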