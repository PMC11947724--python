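{
  "kind": "pattern",
  "directed": true,
  "nodes": [
    {"id": "AP", "role": "AP", "dt_threshold": 0.3, "dt_function": "identity"},
    {"id": "PM", "role": "PM", "dt_threshold": 0.3, "dt_function": "identity"},
    {"id": "TC", "role": "TC", "dt_threshold": 0.3, "dt_function": "identity"},
    {"id": "TI", "role": "TI", "dt_threshold": 0.3, "dt_function": "identity"},
    {"id": "TM", "role": "TM", "dt_threshold": 0.3, "dt_function": "identity"}
  ],
  "edges": [
    {"source": "AP", "target": "TC", "dt_threshold": 0.2, "dt_function": "identity", "dc_threshold": 0.2, "dc_function": "identity", "cv_threshold": 0.2, "cv_function": "identity", "length_bound": 2},
    {"source": "AP", "target": "TI", "dt_threshold": 0.2, "dt_function": "identity", "dc_threshold": 0.2, "dc_function": "identity", "cv_threshold": 0.2, "cv_function": "identity", "length_bound": 2},
    {"source": "PM", "target": "TC", "dt_threshold": 0.2, "dt_function": "identity", "dc_threshold": 0.2, "dc_function": "identity", "cv_threshold": 0.2, "cv_function": "identity", "length_bound": 2},
    {"source": "TC", "target": "TM", "dt_threshold": 0.2, "dt_function": "identity", "dc_threshold": 0.2, "dc_function": "identity", "cv_threshold": 0.2, "cv_function": "identity", "length_bound": 2},
    {"source": "TI", "target": "TC", "dt_threshold": 0.2, "dt_function": "identity", "dc_threshold": 0.2, "dc_function": "identity", "cv_threshold": 0.2, "cv_function": "identity", "length_bound": 2}
  ]
}
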