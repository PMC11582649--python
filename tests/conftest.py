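import numpy as np
import pytest

from tileshot import (
    BackendConfig,
    FixtureSpec,
    LabelSet,
    MockOracleBackend,
    PromptTemplate,
    balanced_test_split,
    generate,
)


@pytest.fixture(scope="session")
def separable_spec():
    """Two classes 8 sigma apart: retrieval and classification are easy."""
    return FixtureSpec(
        classes=("TUM", "NORM"),
        dim=32,
        delta=8.0,
        sigma=1.0,
        patients_per_class=5,
        tiles_per_patient=8,
        seed=11,
    )


@pytest.fixture(scope="session")
def separable_fixture(separable_spec):
    return generate(separable_spec)


@pytest.fixture(scope="session")
def binary_labels():
    return LabelSet(("TUM", "NORM"), aliases={"tumor tissue": "TUM"})


@pytest.fixture(scope="session")
def template():
    return PromptTemplate.default()


@pytest.fixture()
def mock_run(separable_fixture, template):
    """Factory: run a seeded mock pipeline over a balanced split."""
    from tileshot import run_tasks

    manifest, index = separable_fixture

    def _run(k=3, method="knn", error_rate=0.0, seed=0, per_class=5):
        tasks = balanced_test_split(manifest, per_class, seed=seed)
        config = BackendConfig(seed=seed, error_rate=error_rate)
        backend = MockOracleBackend(index, config)
        return run_tasks(
            tasks,
            manifest,
            index,
            backend,
            template,
            k=k,
            method=method,
            sampler_seed=seed,
            backend_config=config,
        )

    return _run


def brute_force_ranking(index, target, label, exclude_same_patient=True):
    """Oracle: exhaustive sort of all eligible cosine similarities."""
    from tileshot import cosine_similarity

    t_vec = index.vector(target)
    t_patient = index.patient_of(target)
    rows = []
    for i, tid in enumerate(index.tile_ids):
        if tid == target or index.labels[i] != label:
            continue
        if (
            exclude_same_patient
            and t_patient is not None
            and index.patient_ids is not None
            and index.patient_ids[i] == t_patient
        ):
            continue
        rows.append((tid, cosine_similarity(t_vec, index.matrix[i])))
    rows.sort(key=lambda r: (-r[1], r[0]))
    return rows
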