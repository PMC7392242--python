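{
  "nodes": ["V", "A", "I", "F", "BV", "BA", "T"],
  "uoea": {
    "edges": [
      ["I", "V", -0.36],
      ["I", "A", 0.25],
      ["F", "V", 0.32],
      ["F", "I", 0.31],
      ["BV", "T", -0.42],
      ["V", "A", -0.18]
    ]
  },
  "poea": {
    "edges": [
      ["I", "V", -0.11],
      ["I", "A", 0.24],
      ["F", "V", 0.40],
      ["F", "A", 0.12],
      ["F", "I", 0.27],
      ["BV", "T", -0.42],
      ["V", "A", 0.21]
    ]
  }
}
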