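import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from tileshot import (
    EmbeddingIndex,
    LabelSet,
    Manifest,
    TileRecord,
    cosine_similarity,
    filter_unanimous,
    neighborhood_composition,
    read_embeddings,
    read_manifest,
    write_embeddings,
    write_manifest,
)
from tileshot.data_model import ManifestFormatError, ManifestValidationError


def _write_tsv(path, rows, header="tile_id\tlabel\tpatient_id\timage_path\tagreement"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")


class TestReadManifest:
    def test_parses_records(self, tmp_path):
        p = tmp_path / "m.tsv"
        _write_tsv(
            p,
            ["t1\tTUM\tp1\t\tyes", "t2\tNORM\tp1\t\tno", "t3\tTUM\t\t\t"],
        )
        m = read_manifest(p, LabelSet(("TUM", "NORM")))
        assert len(m) == 3
        assert m.by_id("t1").agreement is True
        assert m.by_id("t2").agreement is False
        assert m.by_id("t3").patient_id is None

    def test_duplicate_tile_id_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        _write_tsv(p, ["t1\tTUM\t\t\t", "t1\tNORM\t\t\t"])
        with pytest.raises(ManifestValidationError, match="t1"):
            read_manifest(p, LabelSet(("TUM", "NORM")))

    def test_excluded_labels_dropped_at_load(self, tmp_path):
        p = tmp_path / "m.tsv"
        _write_tsv(p, ["t1\tTUM\t\t\t", "t2\tBACK\t\t\t", "t3\tNORM\t\t\t"])
        labels = LabelSet(("TUM", "NORM"), excluded=("BACK",))
        m = read_manifest(p, labels)
        assert len(m) == 2
        assert all(r.label != "BACK" for r in m)

    def test_unknown_label_lists_offenders(self, tmp_path):
        p = tmp_path / "m.tsv"
        _write_tsv(p, ["t1\tTUM\t\t\t", "t2\tWEIRD\t\t\t"])
        with pytest.raises(ManifestValidationError, match="WEIRD"):
            read_manifest(p, LabelSet(("TUM", "NORM")))

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("tile_id\nx\n")
        with pytest.raises(ManifestFormatError, match="label"):
            read_manifest(p, LabelSet(("TUM", "NORM")))

    def test_roundtrip_through_writer(self, tmp_path, separable_fixture):
        manifest, _ = separable_fixture
        p = tmp_path / "out.tsv"
        write_manifest(manifest, p)
        again = read_manifest(p, manifest.label_set)
        assert again.tile_ids == manifest.tile_ids
        assert [r.label for r in again] == [r.label for r in manifest]


class TestFilterUnanimous:
    LS = LabelSet(("A", "B"))

    def _man(self, flags):
        return Manifest(
            [
                TileRecord(f"t{i}", "A", agreement=f)
                for i, f in enumerate(flags)
            ],
            self.LS,
        )

    def test_keeps_only_unanimous(self):
        m = filter_unanimous(self._man([True, False, True, False, True]))
        assert len(m) == 3

    def test_all_unanimous_is_identity(self):
        m = self._man([True] * 4)
        assert filter_unanimous(m).tile_ids == m.tile_ids

    def test_none_unanimous_warns_and_empties(self):
        with pytest.warns(UserWarning, match="empty"):
            m = filter_unanimous(self._man([False, False]))
        assert len(m) == 0

    def test_missing_flag_is_error(self):
        with pytest.raises(ManifestValidationError, match="agreement"):
            filter_unanimous(self._man([True, None]))


class TestCosineSimilarity:
    def test_orthogonal_is_zero(self):
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_scale_invariance(self):
        assert cosine_similarity([1, 1], [2, 2]) == pytest.approx(1.0)

    def test_closed_form_45_degrees(self):
        assert cosine_similarity([1, 0], [1, 1]) == pytest.approx(1 / np.sqrt(2))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            cosine_similarity([0, 0], [1, 0])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            cosine_similarity([1, 0], [1, 0, 0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        a=arrays(np.float64, 6, elements=st.floats(-10, 10)),
        b=arrays(np.float64, 6, elements=st.floats(-10, 10)),
        scale=st.floats(0.01, 100),
    )
    def test_symmetry_self_similarity_and_scaling(self, a, b, scale):
        if np.linalg.norm(a) < 1e-6 or np.linalg.norm(b) < 1e-6:
            return
        assert cosine_similarity(a, a) == pytest.approx(1.0, abs=1e-12)
        s1 = cosine_similarity(a, b)
        assert s1 == pytest.approx(cosine_similarity(b, a), abs=1e-12)
        assert s1 == pytest.approx(cosine_similarity(a * scale, b), abs=1e-11)
        assert -1.0 <= s1 <= 1.0


class TestNeighborhoodComposition:
    def _index(self, vecs, labels):
        return EmbeddingIndex(
            [f"t{i}" for i in range(len(vecs))], np.array(vecs, dtype=float), labels
        )

    def test_homogeneous_neighborhood(self):
        idx = self._index(
            [[1, 0], [0.99, 0.1], [0.98, 0.2], [0.97, 0.3]], ["X", "A", "A", "A"]
        )
        assert neighborhood_composition(idx, "t0", 3) == {"A": 1.0}

    def test_symmetric_split(self):
        idx = self._index(
            [[1, 0], [0, 1], [0, 1], [0, -1], [0, -1]], ["X", "A", "A", "B", "B"]
        )
        assert neighborhood_composition(idx, "t0", 4) == {"A": 0.5, "B": 0.5}

    def test_matches_exhaustive_sort_oracle(self):
        rng = np.random.default_rng(3)
        vecs = np.vstack(
            [rng.normal(2, 1, (12, 5)), rng.normal(-2, 1, (12, 5))]
        )
        labels = ["A"] * 12 + ["B"] * 12
        idx = self._index(vecs, labels)
        target = "t0"
        sims = sorted(
            ((cosine_similarity(idx.vector(target), v), tid, lab)
             for tid, v, lab in zip(idx.tile_ids, vecs, labels)
             if tid != target),
            key=lambda r: (-r[0], r[1]),
        )
        top = sims[:10]
        expected = {
            lab: sum(1 for s in top if s[2] == lab) / 10
            for lab in set(s[2] for s in top)
        }
        assert neighborhood_composition(idx, target, 10) == expected

    def test_fractions_sum_to_one(self, separable_fixture):
        _, idx = separable_fixture
        comp = neighborhood_composition(idx, idx.tile_ids[0], 15)
        assert sum(comp.values()) == pytest.approx(1.0)
        assert all(0 <= f <= 1 for f in comp.values())

    def test_invalid_n_rejected(self, separable_fixture):
        _, idx = separable_fixture
        with pytest.raises(ValueError):
            neighborhood_composition(idx, idx.tile_ids[0], 0)
        with pytest.raises(ValueError):
            neighborhood_composition(idx, idx.tile_ids[0], len(idx))


class TestEmbeddingIO:
    def test_roundtrip_bitwise(self, tmp_path):
        rng = np.random.default_rng(0)
        idx = EmbeddingIndex(
            [f"t{i}" for i in range(10)],
            rng.normal(size=(10, 768)).astype(np.float32),
            labels=["A"] * 5 + ["B"] * 5,
            patient_ids=["p1"] * 5 + [None] * 5,
        )
        write_embeddings(idx, tmp_path / "emb")
        back = read_embeddings(tmp_path / "emb")
        assert back.tile_ids == idx.tile_ids
        assert np.array_equal(back.matrix, idx.matrix)
        assert back.labels == idx.labels
        assert back.patient_ids == idx.patient_ids

    def test_row_count_mismatch_with_manifest(self, tmp_path, separable_fixture):
        manifest, index = separable_fixture
        short = index.subset(index.tile_ids[:-1])
        write_embeddings(short, tmp_path / "emb")
        with pytest.raises(ValueError, match="manifest"):
            read_embeddings(tmp_path / "emb", manifest)

    def test_empty_roundtrip(self, tmp_path):
        idx = EmbeddingIndex([], np.zeros((0, 4), dtype=np.float32))
        write_embeddings(idx, tmp_path / "emb")
        back = read_embeddings(tmp_path / "emb")
        assert len(back) == 0
        assert back.matrix.shape == (0, 4)

    def test_alignment_invariant(self, separable_fixture):
        manifest, index = separable_fixture
        assert manifest.tile_ids == index.tile_ids

    def test_zero_vector_not_admitted(self):
        with pytest.raises(ValueError, match="zero"):
            EmbeddingIndex(["a", "b"], np.array([[1.0, 0.0], [0.0, 0.0]]))


class TestLabelSet:
    def test_alias_to_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            LabelSet(("A",), aliases={"x": "B"})

    def test_duplicate_canonical_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            LabelSet(("A", "A"))

    def test_canonicalize_case_insensitive(self):
        ls = LabelSet(("NORM", "TUM"), aliases={"tumor tissue": "TUM"})
        assert ls.canonicalize(" Norm ") == "NORM"
        assert ls.canonicalize("Tumor Tissue") == "TUM"
        assert ls.canonicalize("???") is None
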