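"""End-to-end task loop: sample exemplars, build prompts, invoke a backend,
parse answers, and collect a result log."""

from __future__ import annotations

import logging
from typing import Sequence

from .backend import BackendConfig, VLMBackend, complete
from .data_model import EmbeddingIndex, EvaluationTask, LabelSet, Manifest
from .evaluation import ResultLog
from .prompting import (
    FAILED,
    ModelResult,
    PromptTemplate,
    build_few_shot,
    build_zero_shot,
    parse_response,
)
from .sampler import KNN, RANDOM, knn_sample, random_sample

logger = logging.getLogger(__name__)


def run_tasks(
    tasks: Sequence[EvaluationTask],
    manifest: Manifest,
    index: EmbeddingIndex,
    backend: VLMBackend,
    template: PromptTemplate,
    k: int = 0,
    method: str = KNN,
    exclude_same_patient: bool = True,
    backend_config: BackendConfig | None = None,
    sampler_seed: int = 0,
    metadata: dict | None = None,
) -> ResultLog:
    """Run every task through sampling, prompting, completion and parsing.

    ``k = 0`` runs zero-shot (no sampling).  Transport failures that
    exhaust retries are recorded as parse failures so the loop never
    aborts; the failure policy at scoring time decides their fate.
    """
    backend_config = backend_config or BackendConfig()
    labels = manifest.label_set
    paths = {r.tile_id: r.image_path for r in manifest}
    log = ResultLog(
        metadata={
            "sampler": method if k > 0 else "zero-shot",
            "k": k,
            "backend": backend.name,
            "template_hash": template.hash(),
            "sampler_seed": sampler_seed,
            "exclude_same_patient": exclude_same_patient,
            **(metadata or {}),
        }
    )
    for i, task in enumerate(tasks):
        context = None
        if k > 0:
            if method == KNN:
                context = knn_sample(
                    index, task.target_tile_id, k, labels.labels,
                    exclude_same_patient,
                )
            elif method == RANDOM:
                context = random_sample(
                    index, task.target_tile_id, k, labels.labels,
                    seed=sampler_seed + i, exclude_same_patient=exclude_same_patient,
                )
            else:
                raise ValueError(f"unknown sampling method {method!r}")
            bundle = build_few_shot(
                template, labels, context, task.target_tile_id, paths
            )
        else:
            bundle = build_zero_shot(
                template, labels, task.target_tile_id,
                paths.get(task.target_tile_id),
            )
        outcome = complete(backend, bundle, backend_config)
        if outcome.ok:
            result = parse_response(outcome.text, labels)
        else:
            result = ModelResult(
                "", None, None, f"<transport failure: {outcome.error}>", FAILED
            )
        log.append(
            task, result,
            context_summary=None if context is None else context.to_json_record(),
        )
    return log
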