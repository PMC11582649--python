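"""Vision-language backend contract, mock oracle, retries and refusals.

Any endpoint that accepts a multimodal chat prompt and returns text can sit
behind :class:`VLMBackend`.  The package ships a deterministic mock oracle
so the full pipeline runs and is tested offline: for few-shot bundles it
answers with the label of the in-context exemplar most cosine-similar to
the target; for zero-shot it answers the target's true label, flipped to a
uniformly random other label with probability ``error_rate``.  Real
endpoints are reached through the optional HTTP adapter in
:mod:`tileshot.http_adapter`, which nothing in the test path imports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np

from .data_model import EmbeddingIndex
from .prompting import PromptBundle

logger = logging.getLogger(__name__)


@dataclass
class BackendConfig:
    """Knobs shared by all backends.

    ``temperature`` defaults to 0.1, the low-variance setting used for
    structured classification answers; ``error_rate`` and ``seed`` only
    affect the mock oracle.
    """

    name: str = "mock"
    temperature: float = 0.1
    max_retries: int = 3
    retry_backoff: float = 0.0  # seconds; kept at 0 in tests
    timeout: float = 60.0
    seed: int = 0
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")


class TransportError(RuntimeError):
    """A retryable transport-level failure (network, rate limit, 5xx)."""


@runtime_checkable
class VLMBackend(Protocol):
    name: str
    max_images: int

    def complete_once(self, bundle: PromptBundle) -> str: ...


@dataclass
class CompletionResult:
    """Outcome of :func:`complete`: raw text or an exhausted-retries record."""

    text: str | None
    attempts: int
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.text is not None


def complete(
    backend: VLMBackend, bundle: PromptBundle, config: BackendConfig
) -> CompletionResult:
    """Invoke a backend with retry-on-transport-failure semantics.

    Oversize bundles fail before any request.  Transport failures are
    retried up to ``max_retries`` attempts; after exhaustion a failure
    record is returned rather than an exception, so a task loop never
    aborts mid-run.
    """
    if bundle.image_count > backend.max_images:
        raise ValueError(
            f"bundle holds {bundle.image_count} images, backend "
            f"{backend.name!r} accepts at most {backend.max_images}"
        )
    last_error = "no attempts made"
    for attempt in range(1, max(config.max_retries, 1) + 1):
        try:
            text = backend.complete_once(bundle)
            return CompletionResult(text=text, attempts=attempt)
        except TransportError as exc:
            last_error = str(exc)
            logger.warning("attempt %d failed: %s", attempt, exc)
            if config.retry_backoff:
                time.sleep(config.retry_backoff * attempt)
    return CompletionResult(text=None, attempts=config.max_retries, error=last_error)


def _stable_rng(*tokens: object) -> np.random.Generator:
    """Generator seeded from a stable hash of the tokens (run-to-run stable)."""
    h = hashlib.sha256(":".join(str(t) for t in tokens).encode()).digest()
    return np.random.default_rng(int.from_bytes(h[:8], "little") % (2**63))


@dataclass
class MockOracleBackend:
    """Deterministic test double standing in for a hosted vision model.

    Needs read access to the embedding index (it 'sees' the images through
    their embeddings).  Given identical (bundle, seed, error_rate) the raw
    text is bit-identical.
    """

    index: EmbeddingIndex
    config: BackendConfig = field(default_factory=BackendConfig)
    name: str = "mock"
    max_images: int = 50

    def complete_once(self, bundle: PromptBundle) -> str:
        target = bundle.target_tile_id
        rng = _stable_rng(self.config.seed, target, bundle.image_count)
        labels = list(bundle.label_order)
        if bundle.k > 0:
            exemplar_ids = bundle.image_tile_ids[:-1]
            sims = self.index.similarities_to(target)
            best = max(
                exemplar_ids, key=lambda t: (sims[self.index.row_of(t)], t)
            )
            # ties broken toward larger similarity then ascending tile_id
            best = min(
                (t for t in exemplar_ids
                 if sims[self.index.row_of(t)] == sims[self.index.row_of(best)]),
                default=best,
            )
            answer = self.index.label_of(best)
            score = float(np.clip((sims[self.index.row_of(best)] + 1) / 2, 0, 1))
            thoughts = (
                f"The target most closely resembles example tile {best}, "
                f"which shows {answer}."
            )
        else:
            answer = self.index.label_of(target)
            score = 0.8
            thoughts = f"The tile's appearance is most consistent with {answer}."
        if self.config.error_rate > 0 and rng.random() < self.config.error_rate:
            others = [lab for lab in labels if lab != answer]
            if others:
                answer = others[rng.integers(len(others))]
                thoughts += " On balance it could instead be " + answer + "."
        return json.dumps(
            {"thoughts": thoughts, "answer": answer, "score": round(score, 4)}
        )


@dataclass
class RefusalInjector:
    """Wrap a backend so a seeded fraction of calls returns a refusal.

    Hosted models sometimes refuse to discuss medical images outright; this
    wrapper exercises the failure-accounting path.  The refusal decision is
    a stable function of (seed, target tile), so a run is reproducible.
    """

    inner: VLMBackend
    rate: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("rate must be in [0, 1]")

    @property
    def name(self) -> str:
        return f"refusal({self.inner.name})"

    @property
    def max_images(self) -> int:
        return self.inner.max_images

    def complete_once(self, bundle: PromptBundle) -> str:
        rng = _stable_rng("refusal", self.seed, bundle.target_tile_id)
        if self.rate > 0 and rng.random() < self.rate:
            return (
                "I'm sorry, but I can't help with analysing medical images."
            )
        return self.inner.complete_once(bundle)


@dataclass
class FlakyBackend:
    """Test wrapper that raises TransportError for the first ``failures``
    calls per target, then delegates; exercises the retry contract."""

    inner: VLMBackend
    failures: int = 2

    def __post_init__(self) -> None:
        self._counts: dict[str, int] = {}

    @property
    def name(self) -> str:
        return f"flaky({self.inner.name})"

    @property
    def max_images(self) -> int:
        return self.inner.max_images

    def complete_once(self, bundle: PromptBundle) -> str:
        seen = self._counts.get(bundle.target_tile_id, 0)
        self._counts[bundle.target_tile_id] = seen + 1
        if seen < self.failures:
            raise TransportError(f"simulated outage #{seen + 1}")
        return self.inner.complete_once(bundle)


class RateLimiter:
    """Token-bucket limiter for hosted endpoints with request quotas."""

    def __init__(self, requests_per_minute: float) -> None:
        if requests_per_minute <= 0:
            raise ValueError("requests_per_minute must be positive")
        self.capacity = requests_per_minute
        self.tokens = requests_per_minute
        self.fill_rate = requests_per_minute / 60.0
        self._last = time.monotonic()

    def acquire(self) -> None:
        now = time.monotonic()
        self.tokens = min(self.capacity, self.tokens + (now - self._last) * self.fill_rate)
        self._last = now
        if self.tokens < 1:
            wait = (1 - self.tokens) / self.fill_rate
            time.sleep(wait)
            self.tokens = 1
        self.tokens -= 1
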