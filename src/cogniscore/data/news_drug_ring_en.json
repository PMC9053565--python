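{
 "language": "en",
 "topic": "society",
 "title": "Police dismantles drug trafficking ring",
 "paragraphs": [
  [
   [
    {"surface": "National", "lemma": "national", "pos": "noun", "ne_tag": "organisation", "chunk": "B-NP"},
    {"surface": "Police", "lemma": "police", "pos": "noun", "ne_tag": "organisation", "chunk": "I-NP"},
    {"surface": "has", "lemma": "have", "pos": "verb", "chunk": "O"},
    {"surface": "dismantled", "lemma": "dismantle", "pos": "verb", "chunk": "O"},
    {"surface": "a", "lemma": "a", "pos": "other", "chunk": "B-NP"},
    {"surface": "dangerous", "lemma": "dangerous", "pos": "adjective", "chunk": "I-NP"},
    {"surface": "drug", "lemma": "drug", "pos": "noun", "chunk": "I-NP"},
    {"surface": "trafficking", "lemma": "trafficking", "pos": "noun", "chunk": "I-NP"},
    {"surface": "ring", "lemma": "ring", "pos": "noun", "chunk": "I-NP"},
    {"surface": "that", "lemma": "that", "pos": "other", "chunk": "O"},
    {"surface": "operated", "lemma": "operate", "pos": "verb", "chunk": "O"},
    {"surface": "in", "lemma": "in", "pos": "other", "chunk": "O"},
    {"surface": "Galicia", "lemma": "galicia", "pos": "noun", "ne_tag": "location", "chunk": "B-NP"},
    {"surface": ",", "lemma": ",", "pos": "other", "chunk": "O"},
    {"surface": "Madrid", "lemma": "madrid", "pos": "noun", "ne_tag": "location", "chunk": "B-NP"},
    {"surface": ",", "lemma": ",", "pos": "other", "chunk": "O"},
    {"surface": "and", "lemma": "and", "pos": "other", "chunk": "O"},
    {"surface": "Alicante", "lemma": "alicante", "pos": "noun", "ne_tag": "location", "chunk": "B-NP"}
   ],
   [
    {"surface": "There", "lemma": "there", "pos": "other", "chunk": "O"},
    {"surface": "were", "lemma": "be", "pos": "verb", "chunk": "O"},
    {"surface": "2569", "lemma": "2569", "pos": "number", "is_numeric": true, "chunk": "O"},
    {"surface": "casualties", "lemma": "casualty", "pos": "noun", "chunk": "B-NP"}
   ]
  ]
 ]
}
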