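{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "cogniscore lexicon",
 "description": "Lexical knowledge base: dictionary entries pointing at synsets, and synsets carrying semantic relations and label hierarchies. UTF-8 JSON.",
 "type": "object",
 "required": ["entries", "synsets"],
 "properties": {
  "language": {"type": "string", "default": "es"},
  "entries": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["lemma", "pos"],
    "properties": {
     "lemma": {"type": "string"},
     "pos": {"enum": ["noun", "verb", "adjective", "adverb"]},
     "synsets": {"type": "array", "items": {"type": "string"}},
     "stem": {
      "type": "string",
      "minLength": 1,
      "description": "lowercase; derived with the language's default stemmer when omitted"
     }
    }
   }
  },
  "synsets": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["id", "pos", "lemmas"],
    "properties": {
     "id": {"type": "string"},
     "pos": {"enum": ["noun", "verb", "adjective", "adverb"]},
     "lemmas": {"type": "array", "items": {"type": "string"}},
     "relations": {
      "type": "object",
      "propertyNames": {
       "enum": ["holonym", "hypernym", "hyponym", "meronym", "related"]
      },
      "additionalProperties": {"type": "array", "items": {"type": "string"}},
      "description": "targets must exist and share the synset's pos; missing inverse directions (hypernym/hyponym, holonym/meronym, related) are completed at load time"
     },
     "wordnet_domain": {
      "type": ["string", "null"],
      "description": "nouns and verbs only"
     },
     "adimen_sumo": {
      "type": ["string", "null"],
      "description": "nouns and verbs only"
     },
     "top_ontology": {"type": "array", "items": {"type": "string"}}
    }
   }
  }
 }
}
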