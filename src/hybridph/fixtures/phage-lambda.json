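{
  "genes": [
    {"name": "cI", "max_level": 2},
    {"name": "cro", "max_level": 3},
    {"name": "cII", "max_level": 1},
    {"name": "N", "max_level": 1}
  ],
  "interactions": [
    {"source": "cro", "target": "cI", "threshold": 3, "sign": "-"},
    {"source": "cII", "target": "cI", "threshold": 1, "sign": "+"},
    {"source": "cI", "target": "cro", "threshold": 2, "sign": "-"},
    {"source": "cro", "target": "cro", "threshold": 3, "sign": "-"},
    {"source": "cI", "target": "cII", "threshold": 2, "sign": "-"},
    {"source": "cro", "target": "cII", "threshold": 3, "sign": "-"},
    {"source": "N", "target": "cII", "threshold": 1, "sign": "+"},
    {"source": "cI", "target": "N", "threshold": 1, "sign": "-"},
    {"source": "cro", "target": "N", "threshold": 2, "sign": "-"}
  ],
  "logic": {
    "cI": "!cro & cII",
    "cro": "!cI & !cro",
    "cII": "!cI & !cro & N",
    "N": "!cI & !cro"
  }
}
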