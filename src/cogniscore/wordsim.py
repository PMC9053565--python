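"""Taxonomy-based word similarity with correction factors.

The score for a word pair of one part of speech is

    s = (1 - gamma) * alpha_s * beta ** d + gamma

where ``alpha_s`` is 0.9 for synonyms and 0.85 otherwise, ``beta`` (0.7
by default) decays the score exponentially with the taxonomy distance
``d``, and ``d`` is treated as 0 whenever the words are synonyms,
linked by a holonym / hypernym / hyponym / meronym / related edge, or
share an Adimen-SUMO / Top-Ontology category.  Identical lemmas score
1.0 outright, and an infinite distance (disconnected or out of
vocabulary) zeroes the decayed term.

The correction factor ``gamma`` lifts pairs the taxonomy undervalues:

* ``gamma = 0.5`` for same-stem pairs not already classified as
  synonyms whose uncorrected similarity is at most 0.85 (word-family
  bonus, e.g. *flor* / *florista*);
* otherwise ``gamma = 0.25`` for non-synonym pairs sharing a WordNet
  domain label (e.g. *madera* / *cartón*, both 'substance');
* otherwise ``gamma = 0``.

Corrections only raise scores: s >= (1 - gamma) * base for every pair.
Reported values are rounded half-away-from-zero to two decimals; the
internal computation stays unrounded.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from math import isinf

from .lexicon import LexiconGraph, RelationSummary, relation_summary


@dataclass(frozen=True)
class SimilarityParams:
    """Tunable constants of the word-similarity metric."""

    alpha_synonym: float = 0.9
    alpha_default: float = 0.85
    beta: float = 0.7
    gamma_domain: float = 0.25
    gamma_stem: float = 0.5
    identical_word_score: float = 1.0
    rounding_decimals: int = 2

    def __post_init__(self) -> None:
        for name in (
            "alpha_synonym",
            "alpha_default",
            "beta",
            "gamma_domain",
            "gamma_stem",
            "identical_word_score",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.beta < 1.0:
            raise ValueError("beta must lie in (0, 1)")
        if self.alpha_synonym < self.alpha_default:
            raise ValueError("alpha_synonym must be >= alpha_default")


DEFAULT_PARAMS = SimilarityParams()


@dataclass(frozen=True)
class WordPairAssessment:
    """Full audit trail of one pair's score: which alpha, distance and
    gamma were used, the uncorrected base, and the final score."""

    word1: str
    word2: str
    pos: str
    alpha_used: float
    distance_used: float
    gamma_used: float
    base_score: float
    score: float

    def rounded(self, decimals: int | None = None) -> float:
        return round_half_away(self.score, decimals if decimals is not None else 2)

    def to_dict(self) -> dict:
        return {
            "word1": self.word1,
            "word2": self.word2,
            "pos": self.pos,
            "alpha_used": self.alpha_used,
            "distance_used": (
                None if isinf(self.distance_used) else self.distance_used
            ),
            "gamma_used": self.gamma_used,
            "base_score": self.base_score,
            "score": self.score,
            "score_rounded": self.rounded(),
        }


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero (0.575 -> 0.58), unlike banker's rounding."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def base_similarity(
    kb: LexiconGraph,
    w1: str,
    w2: str,
    pos: str,
    params: SimilarityParams = DEFAULT_PARAMS,
) -> float:
    """Uncorrected similarity alpha_s * beta ** d (gamma left out)."""
    summary = relation_summary(kb, w1, w2, pos)
    return _base_from_summary(w1, w2, summary, params)


def _base_from_summary(
    w1: str, w2: str, summary: RelationSummary, params: SimilarityParams
) -> float:
    if w1.casefold() == w2.casefold():
        return params.identical_word_score
    d = summary.scoring_distance
    if isinf(d):
        return 0.0
    alpha = params.alpha_synonym if summary.are_synonyms else params.alpha_default
    return alpha * params.beta**d


def select_gamma(
    summary: RelationSummary,
    base: float,
    params: SimilarityParams = DEFAULT_PARAMS,
) -> float:
    """Pick the correction factor for a pair given its relation flags and
    uncorrected score.  Stem takes precedence over domain; synonym pairs
    are never corrected."""
    if summary.are_synonyms:
        return 0.0
    if summary.same_stem and base <= params.alpha_default:
        return params.gamma_stem
    if summary.same_wordnet_domain:
        return params.gamma_domain
    return 0.0


def corrected_score(
    base: float,
    summary: RelationSummary,
    params: SimilarityParams = DEFAULT_PARAMS,
) -> tuple[float, float]:
    """Apply the gamma correction to an uncorrected score.

    Returns ``(gamma_used, score)`` with score = (1-gamma)*base + gamma.
    The base is injectable here on purpose: it lets callers audit the
    correction rules against externally computed uncorrected values.
    """
    gamma = select_gamma(summary, base, params)
    return gamma, (1.0 - gamma) * base + gamma


def word_similarity(
    kb: LexiconGraph,
    w1: str,
    w2: str,
    pos: str,
    params: SimilarityParams = DEFAULT_PARAMS,
) -> WordPairAssessment:
    """Score one same-pos word pair, returning the full assessment."""
    summary = relation_summary(kb, w1, w2, pos)
    base = _base_from_summary(w1, w2, summary, params)
    gamma, score = corrected_score(base, summary, params)
    if w1.casefold() == w2.casefold():
        alpha = params.identical_word_score
    elif summary.are_synonyms:
        alpha = params.alpha_synonym
    else:
        alpha = params.alpha_default
    return WordPairAssessment(
        word1=w1,
        word2=w2,
        pos=pos,
        alpha_used=alpha,
        distance_used=summary.scoring_distance,
        gamma_used=gamma,
        base_score=base,
        score=score,
    )
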