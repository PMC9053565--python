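"""Tolerant matching of numeric quantities.

People rarely retain exact figures from a news item: after hearing
"there were 2569 casualties" a listener will plausibly report "over
2500".  A recalled value is therefore accepted when it is a plausible
rounding of the true quantity: for each power of ten below the number's
magnitude, both the floor and the ceiling multiples count as candidates
(for 2569: 2560, 2570, 2500, 2600, 2000, 3000).

Scoring: an exact match scores 1.0; a rounding candidate scores 0.9
when an accompanying over/under qualifier is consistent with the true
value ("over 2500" for 2569), and 0.7 otherwise — a match that reflects
less understanding of the original information.  Anything else scores 0.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from .annotations import AnnotatedAnswer

QUALIFIERS = ("none", "over", "under")

# qualifier markers that may immediately precede a number, per language
DEFAULT_MARKERS: dict[str, dict[str, str]] = {
    "es": {
        "más de": "over",
        "mas de": "over",
        "por encima de": "over",
        "menos de": "under",
        "por debajo de": "under",
    },
    "en": {
        "over": "over",
        "more than": "over",
        "above": "over",
        "under": "under",
        "less than": "under",
        "below": "under",
    },
}


@dataclass(frozen=True)
class Quantity:
    """A numeric mention: its value and an optional over/under qualifier."""

    value: int
    qualifier: str = "none"
    source_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("quantities are non-negative")
        if self.qualifier not in QUALIFIERS:
            raise ValueError(f"invalid qualifier {self.qualifier!r}")


def rounding_candidates(n: int) -> set[int]:
    """All values ``n`` can plausibly be rounded to.

    For each power of ten 10^k with 1 <= k < number of digits of ``n``,
    include floor(n / 10^k) * 10^k and ceil(n / 10^k) * 10^k.  Exact
    multiples collapse, and ``n`` itself is never a candidate.
    """
    if n < 0:
        raise ValueError("quantities are non-negative")
    out: set[int] = set()
    digits = len(str(n))
    for k in range(1, digits):
        p = 10**k
        out.add((n // p) * p)
        out.add(-(-n // p) * p)
    out.discard(n)
    return out


def score_quantity(gold: Quantity, answer: Quantity) -> float:
    """Score a recalled quantity against the true one.

    Returns one of {0, 0.7, 0.9, 1.0}.  The qualifier is "chosen
    correctly" when it points from the rounded value toward the true
    one: ``over`` when the true value exceeds the stated one, ``under``
    when it falls below.
    """
    if answer.value == gold.value:
        return 1.0
    if answer.value in rounding_candidates(gold.value):
        correct = (answer.qualifier == "over" and gold.value > answer.value) or (
            answer.qualifier == "under" and gold.value < answer.value
        )
        return 0.9 if correct else 0.7
    return 0.0


_DIGITS = re.compile(r"\d+")


def parse_int(text: str) -> int | None:
    """Best-effort integer from a numeric token surface ('2.500' -> 2500)."""
    digits = "".join(_DIGITS.findall(text))
    return int(digits) if digits else None


def load_markers(path: str | Path) -> dict[str, str]:
    """Read a marker lexicon: one ``phrase<TAB>over|under`` per line.

    Blank lines and lines starting with '#' are skipped.
    """
    out: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        phrase, _, direction = line.partition("\t")
        direction = direction.strip()
        if direction not in ("over", "under"):
            raise ValueError(f"marker line {line!r}: direction must be over|under")
        out[phrase.casefold()] = direction
    return out


def extract_quantities(
    answer: AnnotatedAnswer,
    markers: dict[str, str] | None = None,
) -> list[Quantity]:
    """Turn each numeric token of an answer into a :class:`Quantity`.

    A qualifier is attached when a marker phrase from the lexicon
    immediately precedes the number (up to three tokens, longest match
    first).  The default marker lexicon covers Spanish and English.
    """
    if markers is None:
        markers = {**DEFAULT_MARKERS["es"], **DEFAULT_MARKERS["en"]}
    markers = {k.casefold(): v for k, v in markers.items()}
    out: list[Quantity] = []
    toks = answer.tokens
    for i, tok in enumerate(toks):
        if not tok.is_numeric:
            continue
        value = parse_int(tok.lemma) or parse_int(tok.surface)
        if value is None:
            continue
        qualifier = "none"
        for width in (3, 2, 1):
            if i - width < 0:
                continue
            phrase = " ".join(t.surface for t in toks[i - width : i]).casefold()
            if phrase in markers:
                qualifier = markers[phrase]
                break
        out.append(Quantity(value=value, qualifier=qualifier, source_span=(i, i + 1)))
    return out
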