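"""Optional chat-completions HTTP adapter for hosted vision-language models.

This module is deliberately self-contained and is never imported by the
test suite or any offline code path: the pipeline's contract is the
:class:`tileshot.backend.VLMBackend` protocol, and the mock oracle fulfils
it offline.  Point this adapter at any chat-completions-compatible
endpoint; the API key is read from an environment variable and never
logged or persisted.
"""

from __future__ import annotations

import json
import os
import urllib.request
from dataclasses import dataclass

from .backend import TransportError
from .prompting import PromptBundle


@dataclass
class ChatCompletionsBackend:
    """Thin client for a chat-completions endpoint with image support."""

    endpoint: str = "https://api.openai.com/v1/chat/completions"
    model: str = "gpt-4o"
    api_key_env: str = "OPENAI_API_KEY"
    temperature: float = 0.1
    max_tokens: int = 800
    timeout: float = 120.0
    name: str = "chat-completions"
    max_images: int = 50

    def complete_once(self, bundle: PromptBundle) -> str:
        api_key = os.environ.get(self.api_key_env)
        if not api_key:
            raise TransportError(
                f"API key environment variable {self.api_key_env} not set"
            )
        body = json.dumps(
            {
                "model": self.model,
                "temperature": self.temperature,
                "max_tokens": self.max_tokens,
                "messages": bundle.to_chat_messages(),
            }
        ).encode()
        req = urllib.request.Request(
            self.endpoint,
            data=body,
            headers={
                "Content-Type": "application/json",
                "Authorization": f"Bearer {api_key}",
            },
        )
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                payload = json.loads(resp.read())
        except Exception as exc:  # network/HTTP errors are retryable
            raise TransportError(str(exc)) from exc
        try:
            return payload["choices"][0]["message"]["content"]
        except (KeyError, IndexError) as exc:
            raise TransportError(f"malformed response: {payload}") from exc
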