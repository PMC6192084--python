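{
 "class_word": "depression",
 "levels": [
  {
   "name": "normal",
   "index": 1,
   "adverbs": [
    "a little",
    "some",
    "succinct",
    "trifling",
    "light",
    "soft"
   ]
  },
  {
   "name": "serious",
   "index": 2,
   "adverbs": [
    "not a little",
    "severe",
    "grave",
    "deep",
    "intensive",
    "intensified"
   ]
  }
 ],
 "class_level_counts": {
  "normal": 2000000,
  "serious": 8000000
 },
 "directions": {},
 "default_direction": 1,
 "margin": 1.0,
 "beta_convention": "signed",
 "note": "class_level_counts are SYNTHETIC stand-ins: the standalone hit counts of the degree-qualified class terms were never published."
}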