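"""Exception hierarchy for cogniscore.

Every error raised by the library derives from :class:`CogniscoreError`
so callers (and the CLI) can distinguish library failures from bugs.
"""


class CogniscoreError(Exception):
    """Base class for all cogniscore errors."""


class LexiconSchemaError(CogniscoreError):
    """A lexicon file does not match the documented schema.

    The message names the offending record.
    """


class LexiconIntegrityError(CogniscoreError):
    """A lexicon violates a structural invariant (e.g. dangling synset id)."""


class FixtureSpecError(CogniscoreError):
    """A fixture-lexicon description is contradictory or incomplete."""


class UnusableGoldError(CogniscoreError):
    """A gold-standard answer carries no content token; it cannot anchor
    the answer-level similarity metric and signals a question-generation
    defect upstream."""


class TemplateConfigError(CogniscoreError):
    """A question-template set is missing entries or placeholders."""


class IneligibleSentenceError(CogniscoreError):
    """A sentence lacks the syntactic ingredients (main verb, preceding
    noun phrase) required to derive a question and its gold answer.
    Callers should try another sentence."""


class SessionConstructionError(CogniscoreError):
    """A dialogue session cannot be built from the given news item; the
    message names the missing ingredient."""


class CohortIntegrityError(CogniscoreError):
    """Session records and participant profiles disagree (e.g. sessions
    for an unknown user)."""


class CohortSettingsError(CogniscoreError):
    """Invalid synthetic-cohort generator settings."""


class FoldError(CogniscoreError):
    """Cross-validation fold constraints cannot be satisfied."""


class UndefinedRankingError(CogniscoreError):
    """Gain-ratio ranking is undefined (e.g. a single-class sample)."""
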