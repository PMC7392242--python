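{
  "relations": [
    {"label": "R1",  "pair": ["I", "V"],  "unpleasant": "-", "pleasant": "-"},
    {"label": "R2",  "pair": ["I", "A"],  "unpleasant": "+", "pleasant": "+"},
    {"label": "R3",  "pair": ["F", "V"],  "unpleasant": null, "pleasant": "+"},
    {"label": "R4",  "pair": ["F", "A"],  "unpleasant": "-", "pleasant": "-"},
    {"label": "R5",  "pair": ["F", "I"],  "unpleasant": "+", "pleasant": "+"},
    {"label": "R6",  "pair": ["BV", "V"], "unpleasant": "+", "pleasant": "+"},
    {"label": "R7",  "pair": ["BV", "A"], "unpleasant": "-", "pleasant": "-"},
    {"label": "R8",  "pair": ["BA", "V"], "unpleasant": "-", "pleasant": "-"},
    {"label": "R9",  "pair": ["BA", "A"], "unpleasant": "+", "pleasant": "+"},
    {"label": "R10", "pair": ["BV", "I"], "unpleasant": "+", "pleasant": "+"},
    {"label": "R11", "pair": ["BA", "I"], "unpleasant": "+", "pleasant": "+"},
    {"label": "R12", "pair": ["BV", "T"], "unpleasant": "-", "pleasant": "-"},
    {"label": "R13", "pair": ["T", "I"],  "unpleasant": "-", "pleasant": "-"},
    {"label": "R14", "pair": ["V", "A"],  "unpleasant": "-", "pleasant": "+"}
  ]
}
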