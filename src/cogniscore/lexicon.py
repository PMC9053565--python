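"""Lexical knowledge base: synsets, semantic relations, domains and stems.

This module stores the linguistic knowledge the similarity engine needs.
It plays the role that a multilingual WordNet-style repository (synsets
with holonym / hypernym / hyponym / meronym / related links, plus the
WordNet-Domains, Adimen-SUMO and Top-Ontology label hierarchies) plays in
a production deployment, behind a small documented JSON format so the
engine can be exercised and tested on fixture lexicons of any size.

Concepts
--------
* A **synset** groups lemmas of one part of speech that share a meaning;
  two lemmas are *synonyms* when they share a synset.
* Relations link synsets of the same part of speech.  ``hypernym`` /
  ``hyponym`` and ``holonym`` / ``meronym`` are kept as mutual inverses;
  ``related`` is symmetric.  Missing inverse directions are completed at
  load time.
* Noun and verb synsets may carry all three semantic-label kinds
  (WordNet domain, Adimen-SUMO, Top Ontology); adjective and adverb
  synsets carry Top-Ontology labels only, mirroring the sparser coverage
  of those categories in the source resources.
* The taxonomy distance between two words is the minimum number of
  relation edges (any kind, undirected) between any synset of one and
  any synset of the other, within one part of speech.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from math import inf
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .errors import FixtureSpecError, LexiconIntegrityError, LexiconSchemaError
from .stemming import Stemmer, stemmer_for

POS_TAGS = ("noun", "verb", "adjective", "adverb")
RELATION_KINDS = ("holonym", "hypernym", "hyponym", "meronym", "related")
INVERSE_RELATION = {
    "hypernym": "hyponym",
    "hyponym": "hypernym",
    "holonym": "meronym",
    "meronym": "holonym",
    "related": "related",
}


@dataclass
class Synset:
    """A sense shared by one or more lemmas of a single part of speech."""

    id: str
    pos: str
    lemmas: list[str]
    relations: dict[str, list[str]] = field(default_factory=dict)
    wordnet_domain: str | None = None
    adimen_sumo: str | None = None
    top_ontology: list[str] = field(default_factory=list)


@dataclass
class LexEntry:
    """A (lemma, pos) dictionary entry pointing at its senses."""

    lemma: str
    pos: str
    synset_ids: list[str]
    stem: str


@dataclass(frozen=True)
class RelationSummary:
    """Everything the word-similarity scorer needs to know about a pair.

    ``taxonomy_distance`` is the raw shortest-path length; the scorer
    treats it as zero whenever ``are_synonyms`` or ``directly_related``
    holds (synonymy takes precedence over direct relatedness).
    """

    are_synonyms: bool
    directly_related: bool
    same_wordnet_domain: bool
    same_stem: bool
    taxonomy_distance: float  # non-negative int, or math.inf

    @property
    def scoring_distance(self) -> float:
        if self.are_synonyms or self.directly_related:
            return 0
        return self.taxonomy_distance


class LexiconGraph:
    """In-memory lexicon: entries, synsets, and per-pos relation graphs.

    Invariants enforced on construction:

    * every pos tag is one of :data:`POS_TAGS`;
    * every synset id referenced by an entry or a relation resolves to a
      synset of the same pos;
    * hypernym/hyponym and holonym/meronym links are mutual inverses
      (completed automatically when only one direction is given);
    * adjective/adverb synsets carry no WordNet-domain or Adimen-SUMO
      label;
    * lookup by (lemma, pos) is unique and case-insensitive.
    """

    def __init__(
        self,
        entries: Iterable[LexEntry],
        synsets: Iterable[Synset],
        language_tag: str = "es",
        stemmer: Stemmer | None = None,
    ) -> None:
        self.language_tag = language_tag
        self.stemmer: Stemmer = stemmer or stemmer_for(language_tag)
        self.synsets: dict[str, Synset] = {}
        for s in synsets:
            if s.pos not in POS_TAGS:
                raise LexiconSchemaError(f"synset {s.id!r}: invalid pos {s.pos!r}")
            if s.id in self.synsets:
                raise LexiconSchemaError(f"duplicate synset id {s.id!r}")
            if s.pos in ("adjective", "adverb") and (
                s.wordnet_domain is not None or s.adimen_sumo is not None
            ):
                raise LexiconSchemaError(
                    f"synset {s.id!r}: {s.pos} synsets may carry only "
                    "top-ontology labels"
                )
            self.synsets[s.id] = s

        self._check_and_complete_relations()

        self.entries: dict[tuple[str, str], LexEntry] = {}
        for e in entries:
            if e.pos not in POS_TAGS:
                raise LexiconSchemaError(f"entry {e.lemma!r}: invalid pos {e.pos!r}")
            if not e.stem or e.stem != e.stem.casefold():
                raise LexiconSchemaError(
                    f"entry {e.lemma!r}: stem must be non-empty lowercase"
                )
            key = (e.lemma.casefold(), e.pos)
            if key in self.entries:
                raise LexiconSchemaError(
                    f"duplicate entry for lemma {e.lemma!r} pos {e.pos!r}"
                )
            for sid in e.synset_ids:
                target = self.synsets.get(sid)
                if target is None:
                    raise LexiconIntegrityError(
                        f"entry {e.lemma!r}/{e.pos}: dangling synset id {sid!r}"
                    )
                if target.pos != e.pos:
                    raise LexiconIntegrityError(
                        f"entry {e.lemma!r}/{e.pos}: synset {sid!r} has pos "
                        f"{target.pos!r}"
                    )
            self.entries[key] = e

        self._graphs: dict[str, nx.Graph] = {pos: nx.Graph() for pos in POS_TAGS}
        for s in self.synsets.values():
            g = self._graphs[s.pos]
            g.add_node(s.id)
            for targets in s.relations.values():
                for t in targets:
                    g.add_edge(s.id, t)

    def _check_and_complete_relations(self) -> None:
        for s in self.synsets.values():
            for kind, targets in s.relations.items():
                if kind not in RELATION_KINDS:
                    raise LexiconSchemaError(
                        f"synset {s.id!r}: unknown relation kind {kind!r}"
                    )
                for t in targets:
                    other = self.synsets.get(t)
                    if other is None:
                        raise LexiconIntegrityError(
                            f"synset {s.id!r}: dangling {kind} target {t!r}"
                        )
                    if other.pos != s.pos:
                        raise LexiconIntegrityError(
                            f"synset {s.id!r}: {kind} target {t!r} crosses pos"
                        )
        # complete inverses after all targets are known to resolve
        for s in list(self.synsets.values()):
            for kind, targets in list(s.relations.items()):
                inv = INVERSE_RELATION[kind]
                for t in targets:
                    back = self.synsets[t].relations.setdefault(inv, [])
                    if s.id not in back:
                        back.append(s.id)
        for s in self.synsets.values():
            s.relations = {
                k: sorted(set(v)) for k, v in sorted(s.relations.items()) if v
            }

    # -- queries ---------------------------------------------------------

    def lookup(self, lemma: str, pos: str) -> LexEntry | None:
        return self.entries.get((lemma.casefold(), pos))

    def synset_ids_of(self, lemma: str, pos: str) -> list[str]:
        e = self.lookup(lemma, pos)
        return list(e.synset_ids) if e else []

    def stem_of(self, lemma: str, pos: str) -> str:
        e = self.lookup(lemma, pos)
        return e.stem if e else self.stemmer(lemma)

    def graph_for(self, pos: str) -> nx.Graph:
        return self._graphs[pos]

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "language": self.language_tag,
            "entries": [
                {
                    "lemma": e.lemma,
                    "pos": e.pos,
                    "synsets": sorted(e.synset_ids),
                    "stem": e.stem,
                }
                for e in sorted(
                    self.entries.values(), key=lambda e: (e.lemma, e.pos)
                )
            ],
            "synsets": [
                {
                    "id": s.id,
                    "pos": s.pos,
                    "lemmas": sorted(s.lemmas),
                    "relations": s.relations,
                    "wordnet_domain": s.wordnet_domain,
                    "adimen_sumo": s.adimen_sumo,
                    "top_ontology": sorted(s.top_ontology),
                }
                for s in sorted(self.synsets.values(), key=lambda s: s.id)
            ],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), ensure_ascii=False, indent=1, sort_keys=True),
            encoding="utf-8",
        )


def _entry_from_dict(d: Mapping, stemmer: Stemmer) -> LexEntry:
    try:
        lemma = d["lemma"]
        pos = d["pos"]
        synsets = list(d.get("synsets", []))
    except (KeyError, TypeError) as exc:
        raise LexiconSchemaError(f"malformed entry record {d!r}") from exc
    stem = d.get("stem") or stemmer(lemma)
    return LexEntry(lemma=lemma, pos=pos, synset_ids=synsets, stem=stem)


def _synset_from_dict(d: Mapping) -> Synset:
    try:
        return Synset(
            id=d["id"],
            pos=d["pos"],
            lemmas=list(d.get("lemmas", [])),
            relations={k: list(v) for k, v in dict(d.get("relations", {})).items()},
            wordnet_domain=d.get("wordnet_domain"),
            adimen_sumo=d.get("adimen_sumo"),
            top_ontology=list(d.get("top_ontology", [])),
        )
    except (KeyError, TypeError) as exc:
        raise LexiconSchemaError(f"malformed synset record {d!r}") from exc


def lexicon_from_dict(data: Mapping) -> LexiconGraph:
    if not isinstance(data, Mapping) or "synsets" not in data or "entries" not in data:
        raise LexiconSchemaError(
            "lexicon file must be a JSON object with 'entries' and 'synsets'"
        )
    language = data.get("language", "es")
    stemmer = stemmer_for(language)
    synsets = [_synset_from_dict(d) for d in data["synsets"]]
    entries = [_entry_from_dict(d, stemmer) for d in data["entries"]]
    return LexiconGraph(entries, synsets, language_tag=language, stemmer=stemmer)


def load_lexicon(path: str | Path) -> LexiconGraph:
    """Load a lexicon from the documented JSON format.

    Raises :class:`LexiconSchemaError` for malformed records and
    :class:`LexiconIntegrityError` for dangling synset references.
    """
    try:
        data = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise LexiconSchemaError(f"{path}: not valid JSON ({exc})") from exc
    return lexicon_from_dict(data)


# -- distance and relation queries --------------------------------------


def shortest_path_distance(kb: LexiconGraph, w1: str, w2: str, pos: str) -> float:
    """Minimum number of relation edges between any synset of ``w1`` and
    any synset of ``w2`` (all relation kinds, undirected, one pos).

    Returns 0 when the words share a synset, ``math.inf`` when they are
    disconnected or either word is out of vocabulary.
    """
    s1 = kb.synset_ids_of(w1, pos)
    s2 = kb.synset_ids_of(w2, pos)
    if not s1 or not s2:
        return inf
    if set(s1) & set(s2):
        return 0
    # multi-source BFS from all synsets of w1 to the nearest synset of w2
    g = kb.graph_for(pos)
    targets = set(s2)
    seen = set(s1)
    frontier = deque((sid, 0) for sid in s1 if sid in g)
    while frontier:
        node, d = frontier.popleft()
        if node in targets:
            return d
        for nb in g.neighbors(node):
            if nb not in seen:
                seen.add(nb)
                frontier.append((nb, d + 1))
    return inf


def _share_hierarchy_category(a: Synset, b: Synset) -> bool:
    if a.adimen_sumo is not None and a.adimen_sumo == b.adimen_sumo:
        return True
    return bool(set(a.top_ontology) & set(b.top_ontology))


def relation_summary(kb: LexiconGraph, w1: str, w2: str, pos: str) -> RelationSummary:
    """Compute the relation flags and taxonomy distance for a word pair.

    Out-of-vocabulary words are not an error: all graph-derived flags are
    false and the distance is infinite, but the stem comparison (and the
    identity case) still applies, so the stem-based similarity correction
    can fire for OOV pairs.
    """
    if pos not in POS_TAGS:
        raise ValueError(f"invalid pos {pos!r}")
    if w1.casefold() == w2.casefold():
        e = kb.lookup(w1, pos)
        dom = None if e is None else _any_domain(kb, e)
        return RelationSummary(
            are_synonyms=True,
            directly_related=True,
            same_wordnet_domain=dom is not None,
            same_stem=True,
            taxonomy_distance=0,
        )
    e1, e2 = kb.lookup(w1, pos), kb.lookup(w2, pos)
    same_stem = kb.stem_of(w1, pos) == kb.stem_of(w2, pos)
    if e1 is None or e2 is None:
        return RelationSummary(False, False, False, same_stem, inf)

    sets1 = [kb.synsets[i] for i in e1.synset_ids]
    sets2 = [kb.synsets[i] for i in e2.synset_ids]
    ids2 = {s.id for s in sets2}
    are_synonyms = any(s.id in ids2 for s in sets1)

    directly_related = False
    same_domain = False
    for a in sets1:
        for b in sets2:
            if any(b.id in targets for targets in a.relations.values()):
                directly_related = True
            if _share_hierarchy_category(a, b):
                directly_related = True
            if a.wordnet_domain is not None and a.wordnet_domain == b.wordnet_domain:
                same_domain = True
    distance = shortest_path_distance(kb, w1, w2, pos)
    return RelationSummary(
        are_synonyms=are_synonyms,
        directly_related=directly_related,
        same_wordnet_domain=same_domain,
        same_stem=same_stem,
        taxonomy_distance=distance,
    )


def _any_domain(kb: LexiconGraph, e: LexEntry) -> str | None:
    for sid in e.synset_ids:
        d = kb.synsets[sid].wordnet_domain
        if d is not None:
            return d
    return None


# -- fixture generation --------------------------------------------------

_DEFAULT_SPEC_PATH = Path(__file__).parent / "data" / "fixture_lexicon_spec.json"


def default_fixture_spec() -> dict:
    """The fixture description shipped with the package (synthetic
    stand-in for a Spanish WordNet fragment)."""
    return json.loads(_DEFAULT_SPEC_PATH.read_text(encoding="utf-8"))


def build_fixture_lexicon(spec: Mapping | None = None, seed: int = 0) -> LexiconGraph:
    """Build a small deterministic lexicon from a fixture description.

    ``spec`` is a JSON-style mapping with keys ``language``, ``synsets``
    (each a synset record as in the lexicon format; entries are derived
    from synset lemmas) and ``relations`` (triples ``[src, kind, dst]``).
    An optional ``assert_not_synonyms`` list of ``[w1, w2, pos]`` triples
    declares pairs that must not end up synonymous; a violation raises
    :class:`FixtureSpecError` (contradictory description).

    The construction is fully determined by the description; ``seed`` is
    accepted for interface uniformity and recorded nowhere.
    """
    del seed  # construction is deterministic regardless
    if spec is None:
        spec = default_fixture_spec()
    language = spec.get("language", "es")
    stemmer = stemmer_for(language)

    synsets: dict[str, Synset] = {}
    for rec in spec.get("synsets", []):
        s = _synset_from_dict(rec)
        if s.id in synsets:
            raise FixtureSpecError(f"duplicate synset id {s.id!r} in fixture spec")
        synsets[s.id] = s
    for triple in spec.get("relations", []):
        try:
            src, kind, dst = triple
        except (TypeError, ValueError) as exc:
            raise FixtureSpecError(f"malformed relation triple {triple!r}") from exc
        if src not in synsets or dst not in synsets:
            raise FixtureSpecError(f"relation {triple!r} references unknown synset")
        if kind not in RELATION_KINDS:
            raise FixtureSpecError(f"unknown relation kind {kind!r}")
        synsets[src].relations.setdefault(kind, []).append(dst)

    # derive one entry per (lemma, pos), merging senses
    by_key: dict[tuple[str, str], list[str]] = {}
    for s in synsets.values():
        for lemma in s.lemmas:
            by_key.setdefault((lemma, s.pos), []).append(s.id)
    entries = [
        LexEntry(lemma=lemma, pos=pos, synset_ids=sorted(ids), stem=stemmer(lemma))
        for (lemma, pos), ids in sorted(by_key.items())
    ]
    kb = LexiconGraph(entries, synsets.values(), language_tag=language, stemmer=stemmer)

    for w1, w2, pos in spec.get("assert_not_synonyms", []):
        if relation_summary(kb, w1, w2, pos).are_synonyms:
            raise FixtureSpecError(
                f"fixture spec declares ({w1!r}, {w2!r}) non-synonymous but "
                "they share a synset"
            )
    return kb
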