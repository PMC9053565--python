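{
 "language": "es",
 "dichotomous": {
  "person": [
   "¿Has oído hablar de {entity}?",
   "¿Conoces a {entity}?",
   "¿Te suena el nombre de {entity}?",
   "¿Sabes quién es {entity}?"
  ],
  "location": [
   "¿Has estado alguna vez en {entity}?",
   "¿Conoces {entity}?",
   "¿Te suena {entity}?",
   "¿Has visitado {entity}?"
  ]
 },
 "follow_up": {
  "person": {
   "yes": "¿Qué datos conoces de la vida de {entity}?",
   "no": "¿Por qué ha saltado a los medios de comunicación {entity}?",
   "n/a": "¿Qué visión de {entity} nos dan los medios de comunicación?"
  },
  "location": {
   "yes": "Cuéntame qué es lo que más te ha gustado de {entity}",
   "no": "¿Por qué no has estado en {entity}?",
   "n/a": "¿Podrías contarme algo relacionado con {entity}?"
  }
 },
 "wh": {
  "who": "¿Quién {predicate}?",
  "what": "¿Qué dice la noticia que pasará?",
  "which_places": "¿Qué lugares menciona la noticia?"
 }
}
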