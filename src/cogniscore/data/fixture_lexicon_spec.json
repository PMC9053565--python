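{
 "language": "es",
 "comment": "Synthetic fixture lexicon: a small Spanish WordNet-style fragment with synonym groups, taxonomy chains, part-whole links, domain labels and stem families. Covers: a fully annotated mountain record; a shared-domain non-related pair (madera/carton, domain substance, path length 4); a shared-stem non-synonym pair (flor/florista, disconnected); person/profession, dwelling, furniture and verb taxonomies; one isolated synset (zapato).",
 "synsets": [
  {"id": "mountain.n", "pos": "noun", "lemmas": ["montaña", "monte"],
   "wordnet_domain": "Object", "adimen_sumo": "LandArea",
   "top_ontology": ["Geography", "Geology"]},
  {"id": "elevation.n", "pos": "noun", "lemmas": ["elevación"]},
  {"id": "alps.n", "pos": "noun", "lemmas": ["Alpes"]},
  {"id": "volcano.n", "pos": "noun", "lemmas": ["volcán"]},
  {"id": "slope.n", "pos": "noun", "lemmas": ["vertiente"]},
  {"id": "summit.n", "pos": "noun", "lemmas": ["cumbre"]},
  {"id": "mountaineer.n", "pos": "noun", "lemmas": ["montañero", "alpinista"]},

  {"id": "material.n", "pos": "noun", "lemmas": ["material"]},
  {"id": "plant_matter.n", "pos": "noun", "lemmas": ["materia"]},
  {"id": "wood.n", "pos": "noun", "lemmas": ["madera"], "wordnet_domain": "substance"},
  {"id": "product.n", "pos": "noun", "lemmas": ["producto"]},
  {"id": "cardboard.n", "pos": "noun", "lemmas": ["cartón"], "wordnet_domain": "substance"},
  {"id": "paper.n", "pos": "noun", "lemmas": ["papel", "folio"], "wordnet_domain": "substance"},

  {"id": "person.n", "pos": "noun", "lemmas": ["persona", "hombre"]},
  {"id": "teacher.n", "pos": "noun", "lemmas": ["profesor"]},
  {"id": "schoolmaster.n", "pos": "noun", "lemmas": ["maestro"], "wordnet_domain": "person"},
  {"id": "baker.n", "pos": "noun", "lemmas": ["panadero"], "wordnet_domain": "person"},
  {"id": "florist.n", "pos": "noun", "lemmas": ["florista"]},

  {"id": "plant.n", "pos": "noun", "lemmas": ["planta"]},
  {"id": "flower.n", "pos": "noun", "lemmas": ["flor"]},

  {"id": "building.n", "pos": "noun", "lemmas": ["edificio"]},
  {"id": "dwelling.n", "pos": "noun", "lemmas": ["vivienda"]},
  {"id": "home.n", "pos": "noun", "lemmas": ["casa", "hogar"]},
  {"id": "apartment.n", "pos": "noun", "lemmas": ["apartamento", "piso"]},
  {"id": "shop.n", "pos": "noun", "lemmas": ["tienda"]},

  {"id": "furniture.n", "pos": "noun", "lemmas": ["mueble"], "wordnet_domain": "furniture"},
  {"id": "chair.n", "pos": "noun", "lemmas": ["silla"], "wordnet_domain": "furniture"},

  {"id": "shoe.n", "pos": "noun", "lemmas": ["zapato"]},

  {"id": "act.v", "pos": "verb", "lemmas": ["actuar"]},
  {"id": "move.v", "pos": "verb", "lemmas": ["mover"]},
  {"id": "take.v", "pos": "verb", "lemmas": ["llevar"]},
  {"id": "take_out.v", "pos": "verb", "lemmas": ["sacar"]},
  {"id": "break.v", "pos": "verb", "lemmas": ["romper"]},

  {"id": "white.a", "pos": "adjective", "lemmas": ["blanco"], "top_ontology": ["Colour"]},
  {"id": "mountainous.a", "pos": "adjective", "lemmas": ["montañoso", "montuoso"], "top_ontology": ["Physical"]},
  {"id": "dangerous.a", "pos": "adjective", "lemmas": ["peligroso"]},

  {"id": "quickly.r", "pos": "adverb", "lemmas": ["rápidamente", "deprisa"]}
 ],
 "relations": [
  ["mountain.n", "hypernym", "elevation.n"],
  ["mountain.n", "hyponym", "alps.n"],
  ["mountain.n", "hyponym", "volcano.n"],
  ["mountain.n", "meronym", "slope.n"],
  ["mountain.n", "meronym", "summit.n"],
  ["mountain.n", "related", "mountaineer.n"],

  ["plant_matter.n", "hypernym", "material.n"],
  ["wood.n", "hypernym", "plant_matter.n"],
  ["product.n", "hypernym", "material.n"],
  ["cardboard.n", "hypernym", "product.n"],
  ["paper.n", "hypernym", "product.n"],

  ["teacher.n", "hypernym", "person.n"],
  ["schoolmaster.n", "hypernym", "person.n"],
  ["baker.n", "hypernym", "person.n"],
  ["florist.n", "hypernym", "person.n"],

  ["flower.n", "hypernym", "plant.n"],

  ["dwelling.n", "hypernym", "building.n"],
  ["home.n", "hypernym", "dwelling.n"],
  ["apartment.n", "hypernym", "dwelling.n"],
  ["shop.n", "hypernym", "building.n"],

  ["chair.n", "hypernym", "furniture.n"],

  ["move.v", "hypernym", "act.v"],
  ["take.v", "hypernym", "move.v"],
  ["take_out.v", "hypernym", "move.v"],
  ["break.v", "hypernym", "act.v"]
 ],
 "assert_not_synonyms": [
  ["madera", "cartón", "noun"],
  ["flor", "florista", "noun"]
 ]
}
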