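"""Interaction scripts and style-conditioned rephrasing prompts.

The agent delivers an ordered script of items (in the motivating use case, a
32-item readiness-to-change questionnaire).  Each utterance is produced by
asking a language model to rephrase the next item in the currently selected
communicative style; this module builds that prompt string.  No model is
called here: the default renderer is the identity on the prompt, and any
external service can be plugged in behind the same callable interface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np


class ScriptError(ValueError):
    """Raised for malformed or inconsistent interaction scripts."""


@dataclass(frozen=True)
class ScriptItem:
    """One scripted item: a user-facing question with a stable id."""

    item_id: int
    text: str
    response_domain: str = "integer Likert scale 1-5"

    def __post_init__(self) -> None:
        if self.item_id < 1:
            raise ScriptError(f"item_id must be >= 1, got {self.item_id}")
        if not self.text:
            raise ScriptError(f"item {self.item_id} has empty text")


@dataclass(frozen=True)
class StyleDefinition:
    """A named communicative style with its natural-language definition."""

    name: str
    definition: str


#: The two styles the adaptive agent switches between.
DEFAULT_STYLE_DEFINITIONS: dict[str, StyleDefinition] = {
    "neutral": StyleDefinition("neutral", "concise, factual, and emotionally neutral"),
    "enthusiastic": StyleDefinition(
        "enthusiastic", "supportive, motivational, and positively expressive"
    ),
}

_PROMPT_TEMPLATE = (
    "Rephrase the following user-facing question in a {style} manner, "
    "as defined below. Do not alter the meaning or structure of the item.\n"
    "Style definition: {definition}\n"
    "Question: '{item}'"
)


def build_style_prompt(
    style: Union[StyleDefinition, str], item: ScriptItem
) -> str:
    """Build the rephrasing prompt for one item under one style.

    The three-line template is fixed; only the style name, its definition
    and the original item text are substituted.
    """
    if isinstance(style, str):
        try:
            style = DEFAULT_STYLE_DEFINITIONS[style]
        except KeyError:
            raise ScriptError(
                f"unknown style {style!r}; known: "
                f"{sorted(DEFAULT_STYLE_DEFINITIONS)}"
            ) from None
    return _PROMPT_TEMPLATE.format(
        style=style.name, definition=style.definition, item=item.text
    )


def identity_renderer(prompt: str) -> str:
    """Default renderer: returns the prompt unchanged (no external service)."""
    return prompt


def render_item(
    style: Union[StyleDefinition, str],
    item: ScriptItem,
    renderer: Callable[[str], str] = identity_renderer,
) -> str:
    """Build the style prompt and pass it through a pluggable renderer."""
    return renderer(build_style_prompt(style, item))


_PLACEHOLDER_STEMS = (
    "When I think about my current habits, I feel ready to work on them.",
    "I believe changing my routine would make a difference for me.",
    "I have been thinking about whether my behaviour needs to change.",
    "I am already taking steps to improve what I do day to day.",
    "Keeping up the changes I have made takes ongoing effort from me.",
)


def make_default_script(n_items: int = 32, seed: int = 0) -> list[ScriptItem]:
    """Generate a placeholder script of ``n_items`` neutral statements.

    The texts are stand-ins for a real questionnaire (instrument wording is
    supplied by the user via ``read_script``); generation is deterministic
    for a given seed.
    """
    if n_items < 1:
        raise ScriptError(f"n_items must be >= 1, got {n_items}")
    rng = np.random.default_rng(seed)
    items = []
    for k in range(1, n_items + 1):
        stem = _PLACEHOLDER_STEMS[int(rng.integers(len(_PLACEHOLDER_STEMS)))]
        items.append(ScriptItem(item_id=k, text=f"Item {k}: {stem}"))
    return items


def write_script(script: Sequence[ScriptItem], path: Union[str, Path]) -> None:
    """Write a script as a JSON array of ``{"id": int, "text": str}``."""
    _validate_script(script)
    payload = [{"id": it.item_id, "text": it.text} for it in script]
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def read_script(path: Union[str, Path]) -> list[ScriptItem]:
    """Read a JSON script file, validating ids and ordering."""
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ScriptError(f"malformed script JSON in {path}: {exc}") from exc
    if not isinstance(payload, list):
        raise ScriptError(f"script file {path} must contain a JSON array")
    items = [ScriptItem(item_id=int(e["id"]), text=str(e["text"])) for e in payload]
    _validate_script(items)
    return items


def _validate_script(script: Sequence[ScriptItem]) -> None:
    if len(script) == 0:
        raise ScriptError("script contains no items")
    seen: set[int] = set()
    for it in script:
        if it.item_id in seen:
            raise ScriptError(f"duplicate item_id {it.item_id} in script")
        seen.add(it.item_id)
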