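{
  "_comment": "Illustrative reference fatty-acid profiles for the synthetic panel generator. Class fractions are shares of total fatty acids; leaf weights are shares within their class. Orders of magnitude follow typical vegetable-oil compositions; these are NOT nutritional ground truth.",
  "palm": {
    "fa_total": 95.4,
    "class_fractions": {"SFA": 0.49, "MUFA": 0.40, "PUFA": 0.11},
    "leaf_weights": {"FA16:0": 0.89, "FA18:0": 0.09, "FA14:0": 0.02, "FA18:1": 1.0, "FA18:2": 0.95, "FA18:3": 0.05}
  },
  "palm_kernel": {
    "fa_total": 95.0,
    "class_fractions": {"SFA": 0.82, "MUFA": 0.14, "PUFA": 0.04},
    "leaf_weights": {"FA12:0": 0.58, "FA14:0": 0.20, "FA16:0": 0.12, "FA18:0": 0.10, "FA18:1": 1.0, "FA18:2": 1.0}
  },
  "sunflower": {
    "fa_total": 96.0,
    "class_fractions": {"SFA": 0.11, "MUFA": 0.24, "PUFA": 0.65},
    "leaf_weights": {"FA16:0": 0.60, "FA18:0": 0.40, "FA18:1": 1.0, "FA18:2": 0.99, "FA18:3": 0.01}
  },
  "olive": {
    "fa_total": 95.5,
    "class_fractions": {"SFA": 0.14, "MUFA": 0.75, "PUFA": 0.11},
    "leaf_weights": {"FA16:0": 0.80, "FA18:0": 0.20, "FA18:1": 1.0, "FA18:2": 0.92, "FA18:3": 0.08}
  },
  "coconut": {
    "fa_total": 94.5,
    "class_fractions": {"SFA": 0.90, "MUFA": 0.07, "PUFA": 0.03},
    "leaf_weights": {"FA12:0": 0.52, "FA14:0": 0.21, "FA16:0": 0.11, "FA18:0": 0.16, "FA18:1": 1.0, "FA18:2": 1.0}
  },
  "soybean": {
    "fa_total": 95.5,
    "class_fractions": {"SFA": 0.16, "MUFA": 0.24, "PUFA": 0.60},
    "leaf_weights": {"FA16:0": 0.70, "FA18:0": 0.30, "FA18:1": 1.0, "FA18:2": 0.88, "FA18:3": 0.12}
  },
  "rapeseed": {
    "fa_total": 95.0,
    "class_fractions": {"SFA": 0.08, "MUFA": 0.63, "PUFA": 0.29},
    "leaf_weights": {"FA16:0": 0.70, "FA18:0": 0.30, "FA18:1": 1.0, "FA18:2": 0.68, "FA18:3": 0.32}
  },
  "peanut": {
    "fa_total": 95.5,
    "class_fractions": {"SFA": 0.18, "MUFA": 0.48, "PUFA": 0.34},
    "leaf_weights": {"FA16:0": 0.65, "FA18:0": 0.35, "FA18:1": 1.0, "FA18:2": 1.0}
  },
  "cottonseed": {
    "fa_total": 95.0,
    "class_fractions": {"SFA": 0.27, "MUFA": 0.19, "PUFA": 0.54},
    "leaf_weights": {"FA14:0": 0.04, "FA16:0": 0.86, "FA18:0": 0.10, "FA18:1": 1.0, "FA18:2": 1.0}
  }
}
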