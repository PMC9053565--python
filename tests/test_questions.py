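"""Dialogue generation: entities, templates, gold answers, sessions."""

import pytest

import cogniscore as cs
from cogniscore.errors import (
    IneligibleSentenceError,
    SessionConstructionError,
    TemplateConfigError,
)
from cogniscore.questions import classify_reply


class TestEntityExtraction:
    def test_locations_and_organisation(self, drug_ring_news):
        entities = cs.extract_entities(drug_ring_news)
        assert ("National Police", "organisation") in entities
        locations = [e for e, t in entities if t == "location"]
        assert locations == ["Galicia", "Madrid", "Alicante"]

    def test_repeated_mentions_deduplicate(self, drug_ring_news):
        doubled = cs.AnnotatedNewsItem(
            topic=drug_ring_news.topic,
            title=drug_ring_news.title,
            language="en",
            paragraphs=[[drug_ring_news.lead[0], drug_ring_news.lead[0]]],
        )
        assert cs.extract_entities(doubled) == cs.extract_entities(drug_ring_news)

    def test_no_tagged_entities(self, bonds_news):
        stripped = cs.AnnotatedNewsItem(
            topic="economy",
            title="t",
            paragraphs=[
                [
                    [
                        cs.NewsToken("word", "word", "noun")
                        for _ in range(3)
                    ]
                ]
            ],
        )
        assert cs.extract_entities(stripped) == []


class TestDichotomousQuestions:
    def test_entity_substituted_exactly_once(self, templates):
        for seed in range(8):
            q = cs.dichotomous_question("Madrid", "location", templates, seed)
            assert q.count("Madrid") == 1 and "{entity}" not in q

    def test_deterministic_under_seed(self, templates):
        a = cs.dichotomous_question("Galicia", "location", templates, 42)
        b = cs.dichotomous_question("Galicia", "location", templates, 42)
        assert a == b

    def test_draws_from_person_table(self, templates):
        opts = {
            cs.dichotomous_question("X", "person", templates, s) for s in range(64)
        }
        assert opts == {t.format(entity="X") for t in templates.dichotomous["person"]}

    def test_uniform_template_frequencies(self, templates):
        """Over 4000 seeded draws each of the four templates appears
        with frequency 0.25 +/- 0.03."""
        counts: dict[str, int] = {}
        for seed in range(4000):
            q = cs.dichotomous_question("X", "location", templates, seed)
            counts[q] = counts.get(q, 0) + 1
        assert len(counts) == 4
        for c in counts.values():
            assert abs(c / 4000 - 0.25) <= 0.03

    def test_template_set_requires_four_options(self):
        with pytest.raises(TemplateConfigError, match="four"):
            cs.QuestionTemplateSet(
                dichotomous={"person": ["¿{entity}?"], "location": ["¿{entity}?"]},
                follow_up={},
                wh={},
            )


class TestFollowUps:
    @pytest.mark.parametrize(
        ("etype", "reply", "expected"),
        [
            ("person", "yes", "¿Qué datos conoces de la vida de ENTIDAD?"),
            ("location", "no", "¿Por qué no has estado en ENTIDAD?"),
            (
                "person",
                "n/a",
                "¿Qué visión de ENTIDAD nos dan los medios de comunicación?",
            ),
            ("location", "yes", "Cuéntame qué es lo que más te ha gustado de ENTIDAD"),
        ],
    )
    def test_reply_routing(self, templates, etype, reply, expected):
        assert cs.follow_up_question("ENTIDAD", etype, reply, templates) == expected

    def test_organisations_reuse_person_templates(self, templates):
        a = cs.follow_up_question("X", "organisation", "yes", templates)
        b = cs.follow_up_question("X", "person", "yes", templates)
        assert a == b

    @pytest.mark.parametrize(
        ("utterance", "expected"),
        [
            ("sí, claro", "yes"),
            ("No...", "no"),
            ("pues no sabría decirte", "n/a"),
            ("", "n/a"),
        ],
    )
    def test_reply_classification(self, utterance, expected):
        assert classify_reply(utterance) == expected


class TestGoldAnswers:
    def test_who_gold_is_preverbal_noun_phrase(self, drug_ring_news, templates):
        q, gold = cs.wh_question_with_gold(
            drug_ring_news.lead[0], "who", templates, drug_ring_news
        )
        assert gold.text == "National Police"
        assert any(t.pos == "noun" for t in gold.tokens)

    def test_what_gold_is_verb_complex_plus_object(self, bonds_news, templates):
        q, gold = cs.wh_question_with_gold(
            bonds_news.lead[0], "what", templates, bonds_news
        )
        assert gold.text == "It will automatically extend social electric bonds"
        assert any(t.pos == "verb" for t in gold.tokens)

    def test_which_places_gold_lists_all_locations(self, drug_ring_news, templates):
        q, gold = cs.wh_question_with_gold(
            drug_ring_news.lead[0], "which_places", templates, drug_ring_news
        )
        assert [t.surface for t in gold.tokens] == ["Galicia", "Madrid", "Alicante"]
        assert all(t.pos == "noun" for t in gold.tokens)

    def test_sentence_without_verb_is_ineligible(self, templates):
        sentence = [cs.NewsToken("Hola", "hola", "noun", chunk="B-NP")]
        with pytest.raises(IneligibleSentenceError, match="verb"):
            cs.wh_question_with_gold(sentence, "who", templates)

    def test_sentence_without_subject_np_is_ineligible(self, templates):
        sentence = [cs.NewsToken("corre", "correr", "verb")]
        with pytest.raises(IneligibleSentenceError, match="noun phrase"):
            cs.wh_question_with_gold(sentence, "who", templates)


class TestSessions:
    def test_four_questions_and_nonempty_final_gold(self, drug_ring_news, templates):
        session = cs.build_session(drug_ring_news, templates, seed=0)
        assert len(session.questions) == 4
        stages = [q.stage for q in session.questions]
        assert stages == [2, 2, 2, 3]
        final = session.questions[-1]
        assert final.gold is not None and final.gold.tokens

    def test_deterministic(self, drug_ring_news, templates):
        a = cs.build_session(drug_ring_news, templates, seed=11)
        b = cs.build_session(drug_ring_news, templates, seed=11)
        assert a.to_dict() == b.to_dict()

    def test_final_gold_is_usable_by_sim(self, kb, drug_ring_news, templates):
        session = cs.build_session(drug_ring_news, templates, seed=0)
        gold = session.questions[-1].gold
        assert cs.sim(kb, gold, gold).sim == 1.0

    def test_news_without_entities_fails(self, templates):
        bare = cs.AnnotatedNewsItem(
            topic="science",
            title="t",
            paragraphs=[[[cs.NewsToken("algo", "algo", "noun", chunk="B-NP")]]],
        )
        with pytest.raises(SessionConstructionError, match="entities"):
            cs.build_session(bare, templates)
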