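{
  "kind": "mlp",
  "input_shape": [80],
  "num_classes": 2,
  "hidden_layers": [
    {"layer_kind": "dense", "units": 256, "kernel": [], "activation": "relu", "pool": null},
    {"layer_kind": "dense", "units": 256, "kernel": [], "activation": "relu", "pool": null},
    {"layer_kind": "dense", "units": 256, "kernel": [], "activation": "relu", "pool": null}
  ]
}
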