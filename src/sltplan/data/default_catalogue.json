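{
 "medical_features": [
  "sensorineural hearing loss",
  "conductive hearing loss",
  "recurrent otitis media",
  "auditory hypersensitivity",
  "history of ototoxic medication",
  "cleft palate",
  "orofacial hypotonia",
  "dental malocclusion",
  "oromotor impairment with sialorrhea",
  "temporomandibular limitation",
  "chronic respiratory disease",
  "thoracic asymmetry",
  "chronic nasal obstruction",
  "laryngeal pathology",
  "gastroesophageal reflux",
  "dysarthria",
  "dyslalia",
  "expressive dysphasia",
  "oral apraxia",
  "phonological disorder",
  "intellectual disability",
  "autism spectrum disorder",
  "receptive dysphasia",
  "epilepsy",
  "attention deficit"
 ],
 "areas": [
  {
   "name": "hearing",
   "features_mr": [
    0,
    1,
    2,
    3,
    4
   ],
   "dimensions": [
    "cochleo-palpebral reflex present",
    "startle response to sound",
    "turns head toward sound source",
    "identifies common sound objects",
    "localizes sound source without visual cue"
   ]
  },
  {
   "name": "oral structure & function",
   "features_mr": [
    5,
    6,
    7,
    8,
    9
   ],
   "dimensions": [
    "tongue size within normal range",
    "tongue protrusion voluntary",
    "tongue lateralization left-right",
    "tongue elevation to alveolar ridge",
    "adequate speed of tongue movements",
    "tongue tone adequate at rest",
    "dental alignment adequate",
    "dental occlusion adequate",
    "hard palate shape within normal range",
    "soft palate elevation on phonation",
    "palatal reflex present",
    "lip closure at rest",
    "lip retraction",
    "lip protrusion",
    "labial seal during swallowing",
    "maxillary opening within normal range",
    "maxillary lateral mobility",
    "jaw stability during speech",
    "voluntary swallowing present",
    "involuntary swallowing present",
    "chews hard food",
    "chews soft food",
    "sialorrhea absent",
    "oral sensitivity within normal range",
    "coordinated suck-swallow-breathe pattern"
   ]
  },
  {
   "name": "linguistic formulation",
   "features_mr": [
    10,
    11,
    12,
    13,
    14
   ],
   "dimensions": [
    "respiratory frequency within normal range",
    "thorax symmetry",
    "diaphragmatic breathing pattern",
    "costal breathing pattern absent at rest",
    "nasal obstruction absent",
    "adequate exhalation period",
    "adequate inspiration depth",
    "sustained phonation of vowels",
    "voice intensity adequate",
    "breathing-phonation coordination"
   ]
  },
  {
   "name": "expressive language & articulation",
   "features_mr": [
    15,
    16,
    17,
    18,
    19
   ],
   "dimensions": [
    "babbling stage completed",
    "canonical syllable production",
    "jargon with intonation contours",
    "first words produced",
    "two-word combinations produced",
    "intelligible connected speech",
    "uses greetings appropriately",
    "requests objects verbally",
    "takes turns in conversation",
    "maintains topic across turns",
    "uses gestures to supplement speech",
    "initiates communicative interactions",
    "names common objects",
    "names actions in pictures",
    "uses basic adjectives",
    "uses spatial vocabulary",
    "uses temporal vocabulary",
    "age-appropriate expressive vocabulary size",
    "uses category labels",
    "describes object functions",
    "uses plural morphemes",
    "uses verb tense markers",
    "uses subject-verb agreement",
    "uses articles and determiners",
    "produces simple declarative sentences",
    "produces interrogative sentences",
    "produces negative sentences",
    "produces compound sentences",
    "retells a short story in sequence",
    "answers inferential questions",
    "formulates sentences from given words",
    "resolves simple verbal analogies",
    "pronounces vowel phonemes",
    "pronounces phoneme /p/",
    "pronounces phoneme /b/",
    "pronounces phoneme /m/",
    "pronounces phoneme /t/",
    "pronounces phoneme /d/",
    "pronounces phoneme /n/",
    "pronounces phoneme /k/",
    "pronounces phoneme /g/",
    "pronounces phoneme /f/",
    "pronounces phoneme /s/",
    "pronounces phoneme /l/",
    "pronounces simple phoneme /r/",
    "pronounces trilled phoneme /rr/",
    "pronounces phoneme /ch/",
    "pronounces consonant clusters with /l/",
    "pronounces consonant clusters with /r/",
    "pronounces polysyllabic words",
    "produces sentences without phoneme omissions",
    "pronounces diphthongs"
   ]
  },
  {
   "name": "receptive language",
   "features_mr": [
    20,
    21,
    22,
    23,
    24
   ],
   "dimensions": [
    "sustained auditory attention",
    "understands place prepositions",
    "understands age-appropriate vocabulary",
    "understands morphosyntactic structures",
    "follows one-step verbal orders",
    "follows two-step verbal orders",
    "identifies objects by their utility",
    "understands temporal notions",
    "classifies objects into semantic categories",
    "completes sequences of four elements"
   ]
  }
 ]
}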