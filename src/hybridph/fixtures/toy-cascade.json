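{
  "genes": [
    {"name": "p", "max_level": 1, "input": "rise"},
    {"name": "q", "max_level": 1},
    {"name": "r", "max_level": 1}
  ],
  "interactions": [
    {"source": "p", "target": "q", "threshold": 1, "sign": "+"},
    {"source": "p", "target": "r", "threshold": 1, "sign": "+"},
    {"source": "q", "target": "r", "threshold": 1, "sign": "+"}
  ],
  "logic": {
    "q": "p",
    "r": "p & q"
  }
}
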