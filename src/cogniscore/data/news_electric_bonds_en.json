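{
 "language": "en",
 "topic": "economy",
 "title": "Government extends social electric bonds",
 "paragraphs": [
  [
   [
    {"surface": "The", "lemma": "the", "pos": "other", "chunk": "B-NP"},
    {"surface": "Government", "lemma": "government", "pos": "noun", "ne_tag": "organisation", "chunk": "I-NP"},
    {"surface": "will", "lemma": "will", "pos": "verb", "chunk": "O"},
    {"surface": "automatically", "lemma": "automatically", "pos": "adverb", "chunk": "O"},
    {"surface": "extend", "lemma": "extend", "pos": "verb", "chunk": "O"},
    {"surface": "the", "lemma": "the", "pos": "other", "chunk": "B-NP"},
    {"surface": "social", "lemma": "social", "pos": "adjective", "chunk": "I-NP"},
    {"surface": "electric", "lemma": "electric", "pos": "adjective", "chunk": "I-NP"},
    {"surface": "bonds", "lemma": "bond", "pos": "noun", "chunk": "I-NP"},
    {"surface": "until", "lemma": "until", "pos": "other", "chunk": "O"},
    {"surface": "September", "lemma": "september", "pos": "noun", "chunk": "B-NP"},
    {"surface": "15th", "lemma": "15", "pos": "number", "is_numeric": true, "chunk": "I-NP"}
   ]
  ]
 ]
}
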