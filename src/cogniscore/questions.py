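"""Rule-based dialogue generation from annotated news items.

A session around one news item has three stages:

1. **News** — the item (title + lead paragraph) is presented.
2. **User-centred questions** — a dichotomous (yes/no) question built
   from a named entity, followed by two essay questions chosen by the
   user's reply; these relax the user and distract from the fact that
   an assessment is going on.
3. **Attention-demanding question** — a final essay question on a key
   aspect of the item, with an automatically extracted gold-standard
   answer, probing comprehension and short-term memory.

Gold answers for wh-questions come from shallow syntax: for *who*
questions, the noun phrase preceding the main verb; for *what*
questions, that predicate's verb complex plus its object noun phrase
(with a neutral pronoun as subject); for *which places* questions, all
location entities mentioned in the item.

Question templates live in a JSON config (Spanish defaults shipped);
each entity template carries exactly one ``{entity}`` placeholder and
four alternative dichotomous formulations per entity type, one of
which is picked at random per question.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .annotations import AnnotatedAnswer, AnnotatedToken, answer_from_tokens
from .errors import (
    IneligibleSentenceError,
    SessionConstructionError,
    TemplateConfigError,
)

NE_TAGS = ("person", "organisation", "location", "none")
ENTITY_TEMPLATE_TYPES = ("person", "location")
REPLIES = ("yes", "no", "n/a")
WH_KINDS = ("who", "what", "which_places")

_DATA = Path(__file__).parent / "data"

YES_MARKERS = {"sí", "si", "claro", "yes", "yeah", "sure"}
NO_MARKERS = {"no", "nunca", "jamás", "never", "nope"}


@dataclass(frozen=True)
class NewsToken(AnnotatedToken):
    """A news token additionally carrying a named-entity tag and a
    noun-phrase chunk label (IOB: B-NP / I-NP / O)."""

    ne_tag: str = "none"
    chunk: str = "O"

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.ne_tag not in NE_TAGS:
            raise ValueError(f"invalid ne_tag {self.ne_tag!r}")
        if self.chunk not in ("B-NP", "I-NP", "O"):
            raise ValueError(f"invalid chunk label {self.chunk!r}")


Sentence = list[NewsToken]


@dataclass
class AnnotatedNewsItem:
    """A news item split into paragraphs of annotated sentences.

    The first paragraph is the lead; it must exist."""

    topic: str
    title: str
    paragraphs: list[list[Sentence]]
    language: str = "es"

    def __post_init__(self) -> None:
        if not self.paragraphs or not self.paragraphs[0]:
            raise ValueError("a news item needs a non-empty lead paragraph")

    @property
    def lead(self) -> list[Sentence]:
        return self.paragraphs[0]

    def sentences(self) -> list[Sentence]:
        return [s for p in self.paragraphs for s in p]

    def lead_text(self) -> str:
        return " ".join(
            " ".join(t.surface for t in s) for s in self.lead
        )


def news_token_from_dict(d: Mapping) -> NewsToken:
    return NewsToken(
        surface=d["surface"],
        lemma=d.get("lemma", d["surface"]),
        pos=d.get("pos", "other"),
        is_numeric=bool(d.get("is_numeric", d.get("pos") == "number")),
        ne_tag=d.get("ne_tag", "none"),
        chunk=d.get("chunk", "O"),
    )


def load_news(path: str | Path) -> AnnotatedNewsItem:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    return AnnotatedNewsItem(
        topic=data["topic"],
        title=data.get("title", ""),
        language=data.get("language", "es"),
        paragraphs=[
            [[news_token_from_dict(t) for t in sent] for sent in para]
            for para in data["paragraphs"]
        ],
    )


# -- templates -----------------------------------------------------------


@dataclass
class QuestionTemplateSet:
    """Question templates keyed by entity type and user reply."""

    dichotomous: dict[str, list[str]]
    follow_up: dict[str, dict[str, str]]
    wh: dict[str, str]
    language: str = "es"

    def __post_init__(self) -> None:
        for etype in ENTITY_TEMPLATE_TYPES:
            opts = self.dichotomous.get(etype, [])
            if len(opts) != 4:
                raise TemplateConfigError(
                    f"need exactly four dichotomous templates for {etype!r}"
                )
            for t in opts:
                _check_placeholder(t)
            fu = self.follow_up.get(etype, {})
            for reply in REPLIES:
                if reply not in fu:
                    raise TemplateConfigError(
                        f"missing follow-up template for ({etype!r}, {reply!r})"
                    )
                _check_placeholder(fu[reply])

    def dichotomous_for(self, etype: str) -> list[str]:
        # organisations reuse the person set (no dedicated table row)
        return self.dichotomous[_canonical_type(etype)]

    def follow_up_for(self, etype: str, reply: str) -> str:
        return self.follow_up[_canonical_type(etype)][reply]


def _canonical_type(etype: str) -> str:
    return "person" if etype in ("person", "organisation") else etype


def _check_placeholder(template: str) -> None:
    if template.count("{entity}") != 1:
        raise TemplateConfigError(
            f"template {template!r} must contain exactly one {{entity}} placeholder"
        )


def load_templates(path: str | Path | None = None) -> QuestionTemplateSet:
    """Load a template set; with no path, the Spanish defaults ship."""
    if path is None:
        path = _DATA / "templates_es.json"
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    return QuestionTemplateSet(
        dichotomous=data["dichotomous"],
        follow_up=data["follow_up"],
        wh=data["wh"],
        language=data.get("language", "es"),
    )


# -- entity extraction ---------------------------------------------------


def extract_entities(news: AnnotatedNewsItem) -> list[tuple[str, str]]:
    """Contiguous named-entity spans, deduplicated, in order of first
    appearance.  Returns (surface text, entity type) pairs."""
    out: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for sent in news.sentences():
        i = 0
        while i < len(sent):
            tag = sent[i].ne_tag
            if tag == "none":
                i += 1
                continue
            j = i
            while j < len(sent) and sent[j].ne_tag == tag:
                j += 1
            text = " ".join(t.surface for t in sent[i:j])
            key = (text.casefold(), tag)
            if key not in seen:
                seen.add(key)
                out.append((text, tag))
            i = j
    return out


# -- question construction ----------------------------------------------


def classify_reply(utterance: str) -> str:
    """Map a free-form reply to yes / no / n-a by its first word."""
    words = utterance.strip().casefold().split()
    if not words:
        return "n/a"
    head = words[0].strip("¡!¿?.,;")
    if head in YES_MARKERS:
        return "yes"
    if head in NO_MARKERS:
        return "no"
    return "n/a"


def dichotomous_question(
    entity: str,
    etype: str,
    templates: QuestionTemplateSet,
    seed: int | random.Random = 0,
) -> str:
    """Pick one of the four templates uniformly (seeded) and fill it in."""
    opts = templates.dichotomous_for(etype)
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    return opts[rng.randrange(len(opts))].format(entity=entity)


def follow_up_question(
    entity: str,
    etype: str,
    reply: str,
    templates: QuestionTemplateSet,
) -> str:
    if reply not in REPLIES:
        reply = classify_reply(reply)
    return templates.follow_up_for(etype, reply).format(entity=entity)


# -- wh-questions and gold answers --------------------------------------


def _np_chunks(sentence: Sentence) -> list[tuple[int, int]]:
    spans = []
    i = 0
    while i < len(sentence):
        if sentence[i].chunk == "B-NP":
            j = i + 1
            while j < len(sentence) and sentence[j].chunk == "I-NP":
                j += 1
            spans.append((i, j))
            i = j
        else:
            i += 1
    return spans


def _verb_complex(sentence: Sentence) -> tuple[int, int] | None:
    """The first contiguous run of verb/adverb tokens, trimmed to end on
    a verb (auxiliaries and mid-complex adverbs stay inside)."""
    for i, tok in enumerate(sentence):
        if tok.pos == "verb":
            j = i
            last_verb = i
            while j < len(sentence) and sentence[j].pos in ("verb", "adverb"):
                if sentence[j].pos == "verb":
                    last_verb = j
                j += 1
            return (i, last_verb + 1)
    return None


def _content_only(tokens: Sequence[NewsToken]) -> list[AnnotatedToken]:
    # drop determiners and other function words from a gold phrase
    return [
        AnnotatedToken(t.surface, t.lemma, t.pos, t.is_numeric)
        for t in tokens
        if t.pos != "other"
    ]


def wh_question_with_gold(
    sentence: Sentence,
    kind: str,
    templates: QuestionTemplateSet,
    news: AnnotatedNewsItem | None = None,
) -> tuple[str, AnnotatedAnswer]:
    """Build a wh-question over one sentence and extract its gold answer.

    * ``who``  — gold is the noun phrase preceding the main verb.
    * ``what`` — gold is a neutral pronoun plus the verb complex plus
      the object noun phrase that follows it.
    * ``which_places`` — gold is every location entity in the news item
      (``news`` required).

    Raises :class:`IneligibleSentenceError` when the sentence lacks a
    main verb or the required noun phrase; callers pick another
    sentence.
    """
    if kind not in WH_KINDS:
        raise ValueError(f"unknown wh kind {kind!r}")
    if kind == "which_places":
        if news is None:
            raise ValueError("which_places questions need the full news item")
        locations = [e for e, t in extract_entities(news) if t == "location"]
        if not locations:
            raise IneligibleSentenceError("news item mentions no locations")
        tokens = [
            AnnotatedToken(surface=loc, lemma=loc, pos="noun") for loc in locations
        ]
        return templates.wh["which_places"], answer_from_tokens(tokens)

    vc = _verb_complex(sentence)
    if vc is None:
        raise IneligibleSentenceError("sentence has no main verb")
    vstart, vend = vc
    nps = _np_chunks(sentence)
    subject = None
    for start, end in nps:
        if end <= vstart:
            subject = (start, end)  # nearest NP before the verb wins
    if subject is None:
        raise IneligibleSentenceError("no noun phrase precedes the verb")

    if kind == "who":
        gold = _content_only(sentence[subject[0] : subject[1]])
        predicate = " ".join(t.surface for t in sentence[vstart:])
        question = templates.wh["who"].format(predicate=predicate)
        return question, answer_from_tokens(gold)

    # what: pronoun + verb complex + following object NP
    obj = next(((s, e) for s, e in nps if s >= vend), None)
    pronoun_surface = "It" if (news and news.language == "en") else "Eso"
    pronoun = AnnotatedToken(pronoun_surface, pronoun_surface.casefold(), "other")
    gold_tokens = [pronoun] + [
        AnnotatedToken(t.surface, t.lemma, t.pos, t.is_numeric)
        for t in sentence[vstart:vend]
    ]
    if obj is not None:
        gold_tokens += _content_only(sentence[obj[0] : obj[1]])
    return templates.wh["what"], answer_from_tokens(gold_tokens)


# -- session assembly ----------------------------------------------------


@dataclass
class Question:
    text: str
    kind: str  # dichotomous | follow_up | who | what | which_places
    stage: int  # 2 or 3
    gold: AnnotatedAnswer | None = None


@dataclass
class DialogueSession:
    """One complete dialogue: the news presentation plus four questions
    (one dichotomous, two distractor essays, one attention-demanding
    wh-question with a non-empty gold answer)."""

    news: AnnotatedNewsItem
    stage1_text: str
    questions: list[Question] = field(default_factory=list)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "topic": self.news.topic,
            "title": self.news.title,
            "seed": self.seed,
            "stage1": self.stage1_text,
            "questions": [
                {
                    "text": q.text,
                    "kind": q.kind,
                    "stage": q.stage,
                    "gold": q.gold.to_list() if q.gold is not None else None,
                }
                for q in self.questions
            ],
        }


def build_session(
    news: AnnotatedNewsItem,
    templates: QuestionTemplateSet | None = None,
    seed: int = 0,
    reply_path: tuple[str, str] = ("yes", "n/a"),
) -> DialogueSession:
    """Assemble the three-stage dialogue for one news item.

    ``reply_path`` fixes the simulated user replies that route the two
    follow-up questions (live systems classify the actual utterance);
    the construction is deterministic given news, seed and reply path.
    """
    if templates is None:
        templates = load_templates()
    entities = extract_entities(news)
    if not entities:
        raise SessionConstructionError("news item has no tagged entities")
    rng = random.Random(seed)

    e1_text, e1_type = entities[0]
    e2_text, e2_type = entities[1] if len(entities) > 1 else entities[0]
    questions = [
        Question(
            text=dichotomous_question(e1_text, e1_type, templates, rng),
            kind="dichotomous",
            stage=2,
        ),
        Question(
            text=follow_up_question(e1_text, e1_type, reply_path[0], templates),
            kind="follow_up",
            stage=2,
        ),
        Question(
            text=follow_up_question(e2_text, e2_type, reply_path[1], templates),
            kind="follow_up",
            stage=2,
        ),
    ]

    # attention-demanding question: first wh-eligible sentence of the lead
    final: Question | None = None
    for sentence in news.lead:
        for kind in ("who", "what"):
            try:
                text, gold = wh_question_with_gold(sentence, kind, templates, news)
            except IneligibleSentenceError:
                continue
            if gold.tokens:
                final = Question(text=text, kind=kind, stage=3, gold=gold)
                break
        if final is not None:
            break
    if final is None:
        try:
            text, gold = wh_question_with_gold(
                news.lead[0], "which_places", templates, news
            )
            final = Question(text=text, kind="which_places", stage=3, gold=gold)
        except IneligibleSentenceError as exc:
            raise SessionConstructionError(
                "no wh-eligible sentence in the lead paragraph and no "
                "location entities to ask about"
            ) from exc
    questions.append(final)

    return DialogueSession(
        news=news,
        stage1_text=f"{news.title}. {news.lead_text()}".strip(". ") or news.lead_text(),
        questions=questions,
        seed=seed,
    )
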