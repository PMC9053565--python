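"""Answer-level similarity: POS-partitioned best-match aggregation.

A user's free-text answer is scored against the gold-standard answer as

    sim = 0.8 * (sum noun*_i + sum verb*_i) / (N_noun + N_verb)
        + 0.2 * (sum adj*_i  + sum adv*_i)  / (N_adj + N_adv)

where, for the i-th content word of lexical category x in the gold
answer, x*_i is the highest word similarity against all words of the
same category in the user's response.  Nouns and verbs carry most of a
sentence's semantic load and get the 0.8 weight; adjectives and adverbs
provide nuances and get 0.2.  Numeric gold tokens are scored by the
tolerant quantity matcher and aggregated with the nouns.

When the gold answer has no adjectives/adverbs (or, symmetrically, no
nouns/verbs) the orphaned weight is reassigned to the other term so a
verbatim-correct answer still reaches sim = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

from .annotations import AnnotatedAnswer, AnnotatedToken
from .errors import UnusableGoldError
from .lexicon import LexiconGraph
from .numsim import Quantity, extract_quantities, parse_int, score_quantity
from .wordsim import DEFAULT_PARAMS, SimilarityParams, word_similarity

# scorer(gold_token, answer_token) -> similarity in [0, 1]
WordScorer = Callable[[AnnotatedToken, AnnotatedToken], float]

CONTENT_GROUP = ("noun", "verb", "number")  # the 0.8-weight group
MODIFIER_GROUP = ("adjective", "adverb")  # the 0.2-weight group
CONTENT_WEIGHT = 0.8
MODIFIER_WEIGHT = 0.2


@dataclass
class SimBreakdown:
    """The sim score together with everything that produced it."""

    sim: float
    content_term: float
    modifier_term: float
    n_noun: int
    n_verb: int
    n_adj: int
    n_adv: int
    n_number: int
    best_matches: list[tuple[AnnotatedToken, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sim": self.sim,
            "content_term": self.content_term,
            "modifier_term": self.modifier_term,
            "counts": {
                "noun": self.n_noun,
                "verb": self.n_verb,
                "adjective": self.n_adj,
                "adverb": self.n_adv,
                "number": self.n_number,
            },
            "best_matches": [
                {"lemma": t.lemma, "pos": t.pos, "score": s}
                for t, s in self.best_matches
            ],
        }


def _default_scorer(kb: LexiconGraph, params: SimilarityParams) -> WordScorer:
    def scorer(gold_tok: AnnotatedToken, ans_tok: AnnotatedToken) -> float:
        return word_similarity(
            kb, gold_tok.lemma, ans_tok.lemma, gold_tok.pos, params
        ).score

    return scorer


def best_match(
    kb: LexiconGraph,
    gold_token: AnnotatedToken,
    answer: AnnotatedAnswer,
    params: SimilarityParams = DEFAULT_PARAMS,
    markers: dict[str, str] | None = None,
    scorer: WordScorer | None = None,
) -> float:
    """Highest similarity of one gold content word against the answer.

    Numeric gold tokens are matched against the quantities extracted
    from the answer; other tokens against same-pos answer tokens.
    Returns 0 when the answer offers nothing of the category.
    """
    if gold_token.pos == "number":
        value = parse_int(gold_token.lemma) or parse_int(gold_token.surface)
        if value is None:
            return 0.0
        gold_q = Quantity(value=value)
        scores = [
            score_quantity(gold_q, q) for q in extract_quantities(answer, markers)
        ]
        return max(scores, default=0.0)
    candidates = answer.tokens_with_pos(gold_token.pos)
    if scorer is None:
        scorer = _default_scorer(kb, params)
    return max((scorer(gold_token, t) for t in candidates), default=0.0)


def sim(
    kb: LexiconGraph,
    gold: AnnotatedAnswer,
    answer: AnnotatedAnswer,
    params: SimilarityParams = DEFAULT_PARAMS,
    markers: dict[str, str] | None = None,
    scorer: WordScorer | None = None,
) -> SimBreakdown:
    """Score a user answer against the gold standard.

    ``scorer`` overrides the word-level similarity (useful for audits);
    it receives (gold_token, answer_token) and must return a value in
    [0, 1].  Raises :class:`UnusableGoldError` when the gold answer has
    no content token — such a gold cannot anchor the metric and points
    at a question-generation defect.
    """
    gold_content = gold.content_tokens()
    if not gold_content:
        raise UnusableGoldError("gold answer contains no content token")

    matches: list[tuple[AnnotatedToken, float]] = []
    content_scores: list[float] = []
    modifier_scores: list[float] = []
    counts = {"noun": 0, "verb": 0, "adjective": 0, "adverb": 0, "number": 0}
    for tok in gold_content:
        x = best_match(kb, tok, answer, params, markers, scorer)
        matches.append((tok, x))
        counts[tok.pos] += 1
        if tok.pos in CONTENT_GROUP:
            content_scores.append(x)
        else:
            modifier_scores.append(x)

    content_term = (
        sum(content_scores) / len(content_scores) if content_scores else 0.0
    )
    modifier_term = (
        sum(modifier_scores) / len(modifier_scores) if modifier_scores else 0.0
    )
    if content_scores and modifier_scores:
        value = CONTENT_WEIGHT * content_term + MODIFIER_WEIGHT * modifier_term
    elif content_scores:
        value = content_term  # orphaned 0.2 weight reassigned
    else:
        value = modifier_term  # gold is modifiers only

    return SimBreakdown(
        sim=value,
        content_term=content_term,
        modifier_term=modifier_term,
        n_noun=counts["noun"],
        n_verb=counts["verb"],
        n_adj=counts["adjective"],
        n_adv=counts["adverb"],
        n_number=counts["number"],
        best_matches=matches,
    )


def rank_paraphrase_degradation(
    kb: LexiconGraph,
    gold: AnnotatedAnswer,
    answers: Sequence[AnnotatedAnswer],
    params: SimilarityParams = DEFAULT_PARAMS,
    markers: dict[str, str] | None = None,
) -> list[tuple[AnnotatedAnswer, SimBreakdown]]:
    """Sort candidate answers by descending sim; ties keep input order."""
    scored = [(a, sim(kb, gold, a, params, markers)) for a in answers]
    return sorted(scored, key=lambda pair: -pair[1].sim)
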