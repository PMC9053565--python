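# cogniscore

Transparent cognitive assessment from news-driven dialogues.

Conversational systems can entertain elderly users with news items and,
along the way, estimate their comprehension and short-term memory
without the stress of a formal test (the "white-coat effect").
`cogniscore` implements the assessment engine behind such a system:

* a **lexical knowledge base** (synsets, holonym/hypernym/hyponym/
  meronym/related links, WordNet-domain / Adimen-SUMO / Top-Ontology
  labels, stems) with a documented JSON format and a fixture generator;
* **word similarity** `s(w1,w2) = (1−γ)·α_s·β^d + γ`, where α_s is 0.9
  for synonyms and 0.85 otherwise, β = 0.7 decays the score per
  taxonomy step, and the correction γ lifts same-stem word families
  (γ = 0.5) and same-WordNet-domain pairs (γ = 0.25);
* **tolerant numeric matching** — plausible roundings of a quantity
  score 0.7, or 0.9 with a correctly chosen over/under qualifier;
* the answer-level metric
  `sim = 0.8·mean(noun*∪verb*) + 0.2·mean(adj*∪adv*)`, a best-match
  aggregation over the gold answer's content words;
* **question generation** from annotated news: seeded dichotomous
  questions from named entities, reply-routed follow-ups, and
  wh-questions with automatically extracted gold answers;
* a **screening stage**: 11 session-derived features, gain-ratio
  feature ranking, user-grouped k-fold evaluation of pluggable
  classifiers, and a synthetic cohort generator for testing.

See `docs/methods.md` for the full model description and design
rationale.

## Worked example

```python
import cogniscore as cs

kb = cs.build_fixture_lexicon()          # small Spanish fixture lexicon

cs.word_similarity(kb, "monte", "montaña", "noun").score    # 0.9  (synonyms)
cs.word_similarity(kb, "montaña", "elevación", "noun").score  # 0.85 (hypernym)
a = cs.word_similarity(kb, "madera", "cartón", "noun")
(a.base_score, a.gamma_used, a.rounded())  # (0.204..., 0.25, 0.4) shared domain

sorted(cs.rounding_candidates(2569))
# [2000, 2500, 2560, 2570, 2600, 3000]
cs.score_quantity(cs.Quantity(2569), cs.Quantity(2500, "over"))   # 0.9
cs.score_quantity(cs.Quantity(2569), cs.Quantity(2500))           # 0.7
```

Scoring a paraphrase against a reference answer (*un profesor llevó
papel en blanco a su hogar en la montaña*):

```python
gold = cs.answer_from_tokens([
    cs.AnnotatedToken("profesor", "profesor", "noun"),
    cs.AnnotatedToken("llevó", "llevar", "verb"),
    cs.AnnotatedToken("papel", "papel", "noun"),
    cs.AnnotatedToken("blanco", "blanco", "adjective"),
    cs.AnnotatedToken("hogar", "hogar", "noun"),
    cs.AnnotatedToken("montaña", "montaña", "noun"),
])
answer = cs.answer_from_tokens([      # "un hombre llevó folios blancos
    cs.AnnotatedToken("hombre", "hombre", "noun"),      # a su casa del monte"
    cs.AnnotatedToken("llevó", "llevar", "verb"),
    cs.AnnotatedToken("folios", "folio", "noun"),
    cs.AnnotatedToken("blancos", "blanco", "adjective"),
    cs.AnnotatedToken("casa", "casa", "noun"),
    cs.AnnotatedToken("monte", "monte", "noun"),
])
round(cs.sim(kb, gold, answer).sim, 3)   # 0.928 — same meaning, new words
```

A fully paraphrased answer stays high, a partially related one drops
(0.534 for *un hombre sacó madera blanca de su apartamento*) and an
unrelated one collapses (0.229) — the degradation the metric is built
to expose.

Everything is also reachable from the CLI:

```
cogniscore make-fixture --seed 1 --out lexicon.json
cogniscore word-sim --lexicon lexicon.json --pos noun monte montaña
cogniscore num-sim 2569 2500 --qualifier over
cogniscore gen-session --news src/cogniscore/data/news_drug_ring_en.json --seed 2
cogniscore simulate-cohort --n-users 200 --seed 1 --out cohort.json
cogniscore screen --features cohort.json --backend dt --k 10 --seed 1
```

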