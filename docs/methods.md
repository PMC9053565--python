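# Methods

cogniscore scores how well a person's free-text answer to a question
about a news item matches an automatically derived reference answer,
and screens for cognitive impairment from the resulting session
features. This note documents the models, the defaults and why they
are what they are, the synthetic data the tests run on, and the known
limitations.

## Word similarity

For two words of the same lexical category (noun, verb, adjective,
adverb) the score is

    s(w1, w2) = (1 − γ) · α_s · β^d(w1, w2) + γ

* **α_s** — 0.9 when the words are synonyms (share a synset), 0.85
  otherwise.
* **d** — taxonomy distance. It is 0 when the words are synonyms,
  linked by a holonym/hypernym/hyponym/meronym/related edge, or share
  an Adimen-SUMO or Top-Ontology category; otherwise it is the
  shortest path in the relation graph. Disconnected or
  out-of-vocabulary pairs get d = ∞, zeroing the decayed term.
* **β** — depth factor, default 0.7: each hierarchical step between
  the concepts multiplies the score by β.
* **γ** — correction factor for pairs the taxonomy undervalues.
  γ = 0.5 for same-stem pairs that are not synonyms and whose
  uncorrected score is at most 0.85 (word families such as
  *flor*/*florista*); otherwise γ = 0.25 for non-synonym pairs sharing
  a WordNet-domain label (e.g. *madera*/*cartón*, both 'substance');
  otherwise γ = 0. Corrections only raise scores.

Decisions taken where the metric's published description is silent:

* **Identical lemmas score 1.0.** Without this a verbatim-correct
  answer could not reach the metric's ceiling.
* **Stem beats domain** when both corrections apply: a shared stem is
  stronger evidence of relatedness than a shared domain.
* **Synonym pairs are never corrected** (they are already at 0.9).
* **Path semantics.** The shortest path treats all five stored
  relation kinds as undirected edges within one part of speech, and a
  multi-sense word's distance is the minimum over all synset pairs;
  synonymy is true if any sense is shared. This is the standard
  most-generous reading; the alternative (hypernym-only paths) would
  only lengthen distances.
* **Out-of-vocabulary pairs** keep the stem and identity checks (so
  the γ = 0.5 rule can still fire) but all graph-derived flags are
  false.
* **Reporting** rounds half away from zero to two decimals (0.575 →
  0.58); internal computation is unrounded.

The reference corrections (uncorrected 0.27 and 0.10 with a shared
domain → 0.45 and 0.33; 0.15 with a shared stem → 0.58) are audited
through an injectable-base pathway (`corrected_score`), because the
uncorrected values depend on distances in a full Spanish WordNet that
no fixture can reproduce. What the fixture lexicon *does* reproduce
exactly are the structural endpoints: 0.9 for synonyms, 0.85 for
directly related non-synonyms, α·β^d for everything else.

## Numeric quantities

A recalled number matches the true quantity n when it equals n
(score 1.0) or is a plausible rounding of it: for each power of ten
10^k below n's magnitude, the floor and ceiling multiples of 10^k are
candidates (2569 → 2000, 2500, 2560, 2570, 2600, 3000). A candidate
scores 0.9 when an adjoining over/under marker points in the correct
direction ("over 2500" for 2569) and 0.7 otherwise. A wrong-direction
qualifier degrades to 0.7 rather than 0 — the rounded value still
matches; only the direction bonus is withheld. Marker phrases are a
per-language plain-text config (Spanish and English defaults ship).
Numbers written as words are expected to be normalized upstream by the
annotation pipeline.

## Answer similarity (sim)

The gold answer's content words are matched greedily: the i-th gold
word of category x takes the highest word similarity x*_i against all
answer words of the same category. These aggregate as

    sim = 0.8 · mean(noun* ∪ verb*) + 0.2 · mean(adj* ∪ adv*)

Nouns and verbs carry most of a sentence's semantic load; adjectives
and adverbs contribute nuances. Numeric gold tokens are scored by the
quantity matcher and pooled with the nouns (numbers behave as nominal
facts). Function words are ignored. When the gold answer has no
modifier (or no content) group, the orphaned weight is reassigned to
the other term — otherwise the formula divides by zero and a perfect
answer could not score 1. Duplicate gold lemmas each contribute their
own x*_i; lemma comparison is case-insensitive.

Because matching is max-based, sim is monotone: adding tokens to an
answer never lowers its score. This is by design (recall-oriented
scoring of elderly speech) and means verbosity is never punished —
a known limitation, acceptable because the questions elicit short
answers.

## Question generation

Entities (person / organisation / location) are taken from the item's
NE tags in order of first appearance. The dichotomous question picks
uniformly (seeded) among four templates for the entity's type;
follow-up essay questions are routed by the user's reply (yes / no /
anything-else). Organisations reuse the person templates — the
published tables cover only people and places. Templates are
agreement-neutral (no morphological inflection), so one string per
slot suffices.

Gold answers come from shallow syntax on the annotated sentence:

* **who** — the noun phrase nearest before the main verb complex,
  minus function words ("National Police").
* **what** — a neutral pronoun + the verb complex (auxiliaries and
  internal adverbs included) + the object noun phrase that follows
  ("It will automatically extend social electric bonds").
* **which places** — every location entity in the item.

The attention-demanding question uses the first wh-eligible sentence
of the lead paragraph (the lead is the item's summary, so its first
parsable sentence is the best proxy for "key aspect"); sentences
without a main verb or a pre-verbal noun phrase are skipped, and a
places question is the fallback when locations exist.

## Screening

Each participant yields one 11-feature vector: four booleans (focus,
stress, studies, technology), a nominal age band (1–4 over
[60,70], (70,80], (80,90], (90,100]), the mean response length in
characters over all answered questions, and the question-4 sim score
of each of the five sessions. The label is binary: impairment present
(mild or severe) versus absent; the three-level annotation is kept on
the profile.

**Gain ratio** ranks features: information gain over split
information, with numeric features discretized by the supervised
binary split at the midpoint maximizing information gain. Constant or
uninformative features score 0; a feature identical to the label
scores 1.

**Evaluation** is user-grouped k-fold cross-validation (default
k = 10): users are shuffled (seeded) and partitioned so no user
contributes to both training and test. Predictions are pooled —
each user is predicted exactly once — and accuracy, per-class
precision/recall/F-measure and the confusion matrix are computed from
the pooled predictions, which keeps the report internally consistent
(accuracy always agrees with the matrix; totals equal the user
count). Classifier backends satisfy a plain fit/predict contract;
shipped adapters wrap a depth-5-capped decision tree and random
forest, a linear SVM, and Gaussian naive Bayes from scikit-learn —
the evaluation machinery and the gain ratio are implemented here, the
learners are standard.

## Synthetic cohort generator

Real session data from elderly participants cannot be redistributed,
so the screening stage is exercised on a simulated cohort that
mirrors the observed structure:

* impairment prevalence 43% absent / 40% mild / 17% severe;
* per-level answer similarity means ± SD of 0.42 ± 0.17 (absent),
  0.29 ± 0.17 (mild), 0.08 ± 0.10 (severe);
* per-level mean answer lengths 54.2 / 37.8 / 30.8 characters
  (SD 18 — a plausible spread; lengths are clipped at 0);
* focus raises and stress lowers performance (±0.10 on the sim
  scale), and sessions differ in difficulty (fixed shifts, the second
  session easiest, the third hardest).

Each user draws a profile (focus 73%, stress 25%, superior studies
47%, technology skills 57%, age bands 20/50/28/2%) and 5 sessions × 4
questions of sim scores. Draws come from a [0,1]-truncated normal
whose location is solved numerically so the truncated mean equals the
target mean; focus/stress/session effects are mean-centred and scaled
by min(1, 4·m(1−m)) near the scale edges, so the marginal per-level
means stay at the configured values (verified to within three
cluster-aware standard errors). Within-user draws share the profile
effect and are therefore correlated, as real repeated measures are.

What the generator does **not** emulate: silence/refusal patterns of
severely impaired users (lengths are symmetric around the mean rather
than zero-inflated), vocabulary-driven session difficulty, education
× technology interactions, and annotator noise in the impairment
labels. Consequently the classes separate more cleanly than in a real
cohort: the parameter-recovery check (depth-5 decision tree, grouped
10-fold, n = 200) demands ≥ 75% accuracy and chance (50 ± 10%) on
label-permuted data, and passing it shows the pipeline recovers
labels whose signal matches the configured effect sizes — not that
any particular clinical accuracy would be attained in the field.

## Problem sizes and numerics

The fixture lexicon has 37 synsets across four parts of speech —
large enough to contain every relation kind, both correction
configurations, disconnected components and multi-sense words, small
enough that every pairwise invariant (symmetry, bounds, BFS-oracle
agreement) is tested exhaustively rather than sampled. The default
cohort is 200 users (1000 sessions); generation takes well under a
second. All randomness flows from explicit seeds (`random.Random` for
template picks, `numpy` generators for the cohort), so every output
is reproducible byte for byte.

Tie-breaking: equal-sim answers keep input order; equal-gain
discretization thresholds keep the lowest; fold partition uses a
seeded shuffle of the sorted user list. Degenerate inputs are
explicit errors (gold answers without content tokens, single-class
rankings, more folds than users) rather than silent zeros.
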