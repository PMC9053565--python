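from pathlib import Path

import pytest

import cogniscore as cs


@pytest.fixture(scope="session")
def kb() -> cs.LexiconGraph:
    return cs.build_fixture_lexicon()


@pytest.fixture(scope="session")
def templates() -> cs.QuestionTemplateSet:
    return cs.load_templates()


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return Path(cs.__file__).parent / "data"


@pytest.fixture(scope="session")
def drug_ring_news(data_dir) -> cs.AnnotatedNewsItem:
    return cs.load_news(data_dir / "news_drug_ring_en.json")


@pytest.fixture(scope="session")
def bonds_news(data_dir) -> cs.AnnotatedNewsItem:
    return cs.load_news(data_dir / "news_electric_bonds_en.json")


def make_answer(*toks: tuple[str, str, str]) -> cs.AnnotatedAnswer:
    """Build an annotated answer from (surface, lemma, pos) triples."""
    return cs.answer_from_tokens(
        cs.AnnotatedToken(s, l, p, is_numeric=(p == "number")) for s, l, p in toks
    )


@pytest.fixture(scope="session")
def paraphrase_triple(kb):
    """Gold sentence and three answers of decreasing fidelity: a full
    paraphrase, a partially related sentence, and an unrelated one."""
    gold = make_answer(
        ("profesor", "profesor", "noun"),
        ("llevó", "llevar", "verb"),
        ("papel", "papel", "noun"),
        ("blanco", "blanco", "adjective"),
        ("hogar", "hogar", "noun"),
        ("montaña", "montaña", "noun"),
    )
    paraphrase = make_answer(
        ("hombre", "hombre", "noun"),
        ("llevó", "llevar", "verb"),
        ("folios", "folio", "noun"),
        ("blancos", "blanco", "adjective"),
        ("casa", "casa", "noun"),
        ("monte", "monte", "noun"),
    )
    partial = make_answer(
        ("hombre", "hombre", "noun"),
        ("sacó", "sacar", "verb"),
        ("madera", "madera", "noun"),
        ("blanca", "blanco", "adjective"),
        ("apartamento", "apartamento", "noun"),
    )
    unrelated = make_answer(
        ("hombre", "hombre", "noun"),
        ("rompió", "romper", "verb"),
        ("silla", "silla", "noun"),
        ("tienda", "tienda", "noun"),
    )
    return gold, [paraphrase, partial, unrelated]
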