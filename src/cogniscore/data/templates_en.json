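{
 "language": "en",
 "dichotomous": {
  "person": [
   "Have you ever heard about {entity}?",
   "Do you know {entity}?",
   "Does the name {entity} ring a bell?",
   "Do you know who {entity} is?"
  ],
  "location": [
   "Have you ever been to {entity}?",
   "Do you know {entity}?",
   "Does {entity} ring a bell?",
   "Have you visited {entity}?"
  ]
 },
 "follow_up": {
  "person": {
   "yes": "What facts do you know about {entity}'s life?",
   "no": "Why has {entity} jumped into the media?",
   "n/a": "Which is the view of {entity} in the media?"
  },
  "location": {
   "yes": "Tell me what you liked the most about {entity}",
   "no": "Why have you never been to {entity}?",
   "n/a": "Could you tell me anything about {entity}?"
  }
 },
 "wh": {
  "who": "Who {predicate}?",
  "what": "What does the news say will happen?",
  "which_places": "Which places does the news item mention?"
 }
}
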