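"""Annotation contract: token lists with lemma, part of speech and
numeric flags.

Annotation itself (tokenization, lemmatization, tagging) is pluggable
and out of scope here; any upstream analyser can produce these token
lists.  Both gold-standard answers and user responses use the same
shape, serialized as a JSON array of token objects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

CONTENT_POS = ("noun", "verb", "adjective", "adverb", "number")
TOKEN_POS = CONTENT_POS + ("other",)


@dataclass(frozen=True)
class AnnotatedToken:
    """One token with its lemma and coarse part of speech.

    ``pos == "number"`` if and only if ``is_numeric`` — digits are a
    lexical category of their own for scoring purposes.
    """

    surface: str
    lemma: str
    pos: str
    is_numeric: bool = False

    def __post_init__(self) -> None:
        if self.pos not in TOKEN_POS:
            raise ValueError(f"invalid pos {self.pos!r} for token {self.surface!r}")
        if (self.pos == "number") != self.is_numeric:
            raise ValueError(
                f"token {self.surface!r}: pos 'number' and is_numeric must agree"
            )


@dataclass
class AnnotatedAnswer:
    """An ordered token list plus the raw text it came from.

    The token list may be empty (silent answers are valid input to the
    scorer and simply score zero)."""

    tokens: list[AnnotatedToken] = field(default_factory=list)
    text: str = ""

    def content_tokens(self) -> list[AnnotatedToken]:
        return [t for t in self.tokens if t.pos in CONTENT_POS]

    def tokens_with_pos(self, pos: str) -> list[AnnotatedToken]:
        return [t for t in self.tokens if t.pos == pos]

    def to_list(self) -> list[dict]:
        return [
            {
                "surface": t.surface,
                "lemma": t.lemma,
                "pos": t.pos,
                "is_numeric": t.is_numeric,
            }
            for t in self.tokens
        ]


def token_from_dict(d: Mapping) -> AnnotatedToken:
    return AnnotatedToken(
        surface=d["surface"],
        lemma=d.get("lemma", d["surface"]),
        pos=d.get("pos", "other"),
        is_numeric=bool(d.get("is_numeric", d.get("pos") == "number")),
    )


def answer_from_tokens(tokens: Iterable[AnnotatedToken]) -> AnnotatedAnswer:
    toks = list(tokens)
    return AnnotatedAnswer(tokens=toks, text=" ".join(t.surface for t in toks))


def load_answer(path: str | Path) -> AnnotatedAnswer:
    """Read an annotated answer from a JSON array of token objects."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    return answer_from_tokens(token_from_dict(d) for d in data)


def save_answer(answer: AnnotatedAnswer, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(answer.to_list(), ensure_ascii=False, indent=1),
        encoding="utf-8",
    )
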