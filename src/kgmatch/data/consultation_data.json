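{
  "kind": "data",
  "directed": true,
  "nodes": [
    {"id": "Drug", "role": "TM", "name": "Drug", "dt": 0.6},
    {"id": "Helen", "role": "AP", "name": "Helen", "dt": 0.8},
    {"id": "Meg", "role": "PM", "name": "Meg", "dt": 0.6},
    {"id": "Operation", "role": "TM", "name": "Operation", "dt": 0.7},
    {"id": "RATS", "role": "TI", "name": "RATS", "dt": 0.7},
    {"id": "SLCLIA", "role": "TC", "name": "SLCLIA", "dt": 0.9}
  ],
  "edges": [
    {"source": "Drug", "target": "Operation", "dt_trust": 0.5, "dc": 0.8, "cv": 0.9},
    {"source": "Helen", "target": "RATS", "dt_trust": 0.6, "dc": 0.8, "cv": 0.7},
    {"source": "Helen", "target": "SLCLIA", "dt_trust": 0.7, "dc": 0.9, "cv": 0.8},
    {"source": "Meg", "target": "SLCLIA", "dt_trust": 0.6, "dc": 0.8, "cv": 0.8},
    {"source": "RATS", "target": "SLCLIA", "dt_trust": 0.6, "dc": 0.7, "cv": 0.9},
    {"source": "SLCLIA", "target": "Drug", "dt_trust": 0.5, "dc": 0.7, "cv": 0.5},
    {"source": "SLCLIA", "target": "Operation", "dt_trust": 0.5, "dc": 0.6, "cv": 0.6}
  ]
}
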