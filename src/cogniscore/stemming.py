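"""Deterministic suffix-stripping stemmers.

Word-family detection (the stem-based similarity correction) only needs a
crude, reproducible notion of a shared stem — e.g. *flor* 'flower' and
*florista* 'florist' must map to the same stem.  The stemmer contract is a
plain callable ``str -> str`` so heavier morphological analysers can be
plugged in per language; the defaults below strip one derivational or
inflectional suffix from a longest-match table and never shorten a word
below three characters.
"""

from __future__ import annotations

from typing import Callable

Stemmer = Callable[[str], str]

# Longest-match-first suffix tables. One pass, one suffix.
_SPANISH_SUFFIXES = (
    "amiento", "imiento", "aciones", "adoras", "adores", "ación",
    "ción", "mente", "adora", "ador", "istas", "ista", "ismo",
    "anza", "able", "ible", "eros", "eras", "oso", "osa", "ivo",
    "iva", "ero", "era", "es", "os", "as", "a", "o", "e", "s",
)

_ENGLISH_SUFFIXES = (
    "ations", "ation", "ness", "ment", "ings", "ing", "ers",
    "ies", "er", "ed", "ly", "es", "s",
)

_MIN_STEM = 3


def _strip(word: str, suffixes: tuple[str, ...]) -> str:
    w = word.casefold()
    for suf in suffixes:
        if w.endswith(suf) and len(w) - len(suf) >= _MIN_STEM:
            return w[: -len(suf)]
    return w


def spanish_stem(word: str) -> str:
    return _strip(word, _SPANISH_SUFFIXES)


def english_stem(word: str) -> str:
    return _strip(word, _ENGLISH_SUFFIXES)


_BY_LANGUAGE: dict[str, Stemmer] = {
    "es": spanish_stem,
    "en": english_stem,
}


def stemmer_for(language_tag: str) -> Stemmer:
    """Return the default stemmer for a BCP-47-ish language tag.

    Unknown languages fall back to the Spanish table (the system's primary
    language); the result is still deterministic and lowercase.
    """
    base = language_tag.split("-")[0].casefold()
    return _BY_LANGUAGE.get(base, spanish_stem)
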