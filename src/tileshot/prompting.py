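"""Prompt assembly and structured-answer parsing.

A prompt bundle is an ordered multimodal message sequence: one system part,
a user part enumerating the labels and (for few-shot) announcing the
exemplar sequence, then k rounds of captioned exemplar images cycling
through the label set, and finally the target image.  A few-shot bundle
therefore contains exactly k * n_labels + 1 images.  The model is asked to
answer as a JSON object ``{"thoughts": ..., "answer": ..., "score": ...}``;
:func:`parse_response` extracts and canonicalizes that answer.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

from .data_model import LabelSet
from .sampler import FewShotContext

logger = logging.getLogger(__name__)

OK = "ok"
FAILED = "failed"
UNMAPPED = "unmapped"

_FENCE_RE = re.compile(r"```(?:json)?\s*(.*?)\s*```", re.DOTALL)
_COMMENT_RE = re.compile(r"^#.*\n", re.MULTILINE)


def _load_asset(name: str) -> str:
    text = resources.files("tileshot.templates").joinpath(name).read_text()
    return _COMMENT_RE.sub("", text)


@dataclass(frozen=True)
class PromptTemplate:
    """The text assets a run is built from; hashed into the run log."""

    system: str
    zero_shot_user: str
    few_shot_user: str
    caption: str
    closing: str
    guidelines: str = ""

    def __post_init__(self) -> None:
        if "{y}" not in self.caption:
            raise ValueError("caption template must contain the {y} placeholder")

    @classmethod
    def default(cls, guidelines: str = "") -> "PromptTemplate":
        return cls(
            system=_load_asset("system.txt"),
            zero_shot_user=_load_asset("user_zero_shot.txt"),
            few_shot_user=_load_asset("user_few_shot.txt"),
            caption=_load_asset("exemplar_caption.txt").strip(),
            closing=_load_asset("closing.txt"),
            guidelines=guidelines,
        )

    def hash(self) -> str:
        h = hashlib.sha256()
        for part in (
            self.system,
            self.zero_shot_user,
            self.few_shot_user,
            self.caption,
            self.closing,
            self.guidelines,
        ):
            h.update(part.encode())
            h.update(b"\x00")
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class MessagePart:
    role: str  # "system" | "user"
    kind: str  # "text" | "image"
    text: str | None = None
    tile_id: str | None = None
    png_bytes: bytes | None = None


@dataclass
class PromptBundle:
    """Ordered multimodal message parts ready for a chat-completions call."""

    parts: list[MessagePart]
    target_tile_id: str
    k: int
    label_order: tuple[str, ...]
    template_hash: str
    context: FewShotContext | None = None

    @property
    def image_count(self) -> int:
        return sum(1 for p in self.parts if p.kind == "image")

    @property
    def image_tile_ids(self) -> list[str]:
        return [p.tile_id for p in self.parts if p.kind == "image"]

    def to_chat_messages(self) -> list[dict]:
        """Render as a generic chat-completions message array.

        Images are embedded as base64 PNG data URLs; parts with no bytes
        (image-by-reference only) raise, since a real endpoint needs pixels.
        """
        import base64

        messages: list[dict] = []
        system_parts = [p for p in self.parts if p.role == "system"]
        messages.append(
            {"role": "system", "content": "".join(p.text or "" for p in system_parts)}
        )
        content: list[dict] = []
        for p in self.parts:
            if p.role == "system":
                continue
            if p.kind == "text":
                content.append({"type": "text", "text": p.text})
            else:
                if p.png_bytes is None:
                    raise ValueError(
                        f"image part {p.tile_id!r} has no bytes; cannot render"
                    )
                b64 = base64.b64encode(p.png_bytes).decode()
                content.append(
                    {
                        "type": "image_url",
                        "image_url": {"url": f"data:image/png;base64,{b64}"},
                    }
                )
        messages.append({"role": "user", "content": content})
        return messages


def _read_image(image_path: str | None) -> bytes | None:
    if image_path is None:
        return None
    p = Path(image_path)
    if not p.exists():
        raise FileNotFoundError(f"image not readable: {image_path}")
    return p.read_bytes()


def _label_enumeration(labels: LabelSet) -> str:
    return ", ".join(labels.labels)


def build_zero_shot(
    template: PromptTemplate,
    labels: LabelSet,
    target_tile_id: str,
    target_image_path: str | None = None,
) -> PromptBundle:
    """System part + user text (label enumeration, reasoning instruction,
    guidelines) + the single target image."""
    if len(labels) == 0:
        raise ValueError("label set is empty")
    user = template.zero_shot_user.format(
        label_options=_label_enumeration(labels),
        guidelines=template.guidelines,
    )
    parts = [
        MessagePart("system", "text", text=template.system),
        MessagePart("user", "text", text=user),
        MessagePart(
            "user",
            "image",
            tile_id=target_tile_id,
            png_bytes=_read_image(target_image_path),
        ),
    ]
    return PromptBundle(
        parts=parts,
        target_tile_id=target_tile_id,
        k=0,
        label_order=labels.labels,
        template_hash=template.hash(),
    )


def build_few_shot(
    template: PromptTemplate,
    labels: LabelSet,
    context: FewShotContext,
    target_tile_id: str,
    image_path_of: Mapping[str, str | None] | None = None,
) -> PromptBundle:
    """Interleave captioned exemplars in k label-cycling rounds, target last.

    Round r shows the r-th most similar exemplar of every label, in LabelSet
    order; each exemplar is a caption ("The following image contains {y}:")
    immediately followed by its image.  With k = 0 this reduces to the
    zero-shot bundle.
    """
    if context.k == 0:
        return build_zero_shot(
            template,
            labels,
            target_tile_id,
            (image_path_of or {}).get(target_tile_id),
        )
    if tuple(context.label_order) != labels.labels:
        raise ValueError(
            f"context label order {context.label_order} does not match "
            f"label set {labels.labels}"
        )
    by_label = context.per_label()
    for lab in labels.labels:
        if len(by_label.get(lab, [])) != context.k:
            raise ValueError(
                f"context holds {len(by_label.get(lab, []))} exemplars for "
                f"{lab!r}, expected {context.k}"
            )
    paths = image_path_of or {}
    user = template.few_shot_user.format(
        label_options=_label_enumeration(labels),
        guidelines=template.guidelines,
    )
    parts = [
        MessagePart("system", "text", text=template.system),
        MessagePart("user", "text", text=user),
    ]
    for round_exemplars in context.rounds():
        for ex in round_exemplars:
            parts.append(
                MessagePart(
                    "user", "text", text=template.caption.format(y=ex.label)
                )
            )
            parts.append(
                MessagePart(
                    "user",
                    "image",
                    tile_id=ex.tile_id,
                    png_bytes=_read_image(paths.get(ex.tile_id)),
                )
            )
    parts.append(MessagePart("user", "text", text=template.closing))
    parts.append(
        MessagePart(
            "user",
            "image",
            tile_id=target_tile_id,
            png_bytes=_read_image(paths.get(target_tile_id)),
        )
    )
    return PromptBundle(
        parts=parts,
        target_tile_id=target_tile_id,
        k=context.k,
        label_order=labels.labels,
        template_hash=template.hash(),
        context=context,
    )


@dataclass
class ModelResult:
    """A parsed model answer with its raw text and parse status."""

    thoughts: str
    answer: str | None
    score: float | None
    raw: str
    status: str  # OK | FAILED | UNMAPPED


def label_aliases(labels: LabelSet, extra: Mapping[str, str] | None = None) -> dict:
    """Total lowercase alias map (identity entries always present).

    ``extra`` entries come from run configuration and must reference
    canonical labels only; an alias claimed by two labels is a config error.
    """
    base = labels.alias_map()
    for alias, target in (extra or {}).items():
        if target not in labels:
            raise ValueError(f"alias {alias!r} maps to unknown label {target!r}")
        key = alias.strip().lower()
        if key in base and base[key] != target:
            raise ValueError(
                f"alias {alias!r} maps to both {base[key]!r} and {target!r}"
            )
        base[key] = target
    return base


def parse_response(raw: str, labels: LabelSet) -> ModelResult:
    """Extract {thoughts, answer, score} from a raw model response.

    Markdown code fences are stripped before JSON parsing; the answer is
    canonicalized through the alias map (case-insensitive, whitespace
    stripped).  Non-JSON text or a missing answer field yields status
    ``failed``; an answer matching no canonical label or alias yields
    ``unmapped``.  Scores outside [0, 1] are clamped with a warning.
    """
    text = raw.strip()
    m = _FENCE_RE.search(text)
    if m:
        text = m.group(1)
    try:
        obj = json.loads(text)
    except (json.JSONDecodeError, TypeError):
        return ModelResult("", None, None, raw, FAILED)
    if not isinstance(obj, dict) or "answer" not in obj:
        return ModelResult("", None, None, raw, FAILED)
    thoughts = str(obj.get("thoughts", ""))
    score = obj.get("score")
    if score is not None:
        try:
            score = float(score)
        except (TypeError, ValueError):
            score = None
        else:
            if not 0.0 <= score <= 1.0:
                logger.warning("score %s outside [0, 1]; clamping", score)
                score = min(max(score, 0.0), 1.0)
    answer = labels.canonicalize(str(obj["answer"]))
    if answer is None:
        return ModelResult(thoughts, None, score, raw, UNMAPPED)
    return ModelResult(thoughts, answer, score, raw, OK)
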