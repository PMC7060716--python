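{
  "name": "adenine",
  "atoms": [
    ["N1", "N"],
    ["C2", "C"],
    ["N3", "N"],
    ["C4", "C"],
    ["C5", "C"],
    ["C6", "C"],
    ["N6", "N"],
    ["N7", "N"],
    ["C8", "C"],
    ["N9", "N"]
  ],
  "bonds": [
    ["N1", "C2"],
    ["C2", "N3"],
    ["N3", "C4"],
    ["C4", "C5"],
    ["C5", "C6"],
    ["C6", "N1"],
    ["C6", "N6"],
    ["C5", "N7"],
    ["N7", "C8"],
    ["C8", "N9"],
    ["N9", "C4"]
  ],
  "donor_atoms": ["N6"],
  "acceptor_atoms": ["N1", "N3", "N7"],
  "weak_ch_donor_atoms": ["C2", "C8"],
  "attachment_atoms": ["N9"],
  "edge_map": {
    "N1": ["watson_crick"],
    "C2": ["watson_crick", "sugar"],
    "N3": ["sugar"],
    "N6": ["watson_crick", "hoogsteen"],
    "N7": ["hoogsteen"],
    "C8": ["hoogsteen"],
    "N9": ["sugar"]
  },
  "edge_refs": {
    "N6": {"watson_crick": "N1", "hoogsteen": "N7"},
    "C2": {"watson_crick": "N1", "sugar": "N3"}
  },
  "reference_coords": {
    "N1": [-2.051, 0.7738, 0.0],
    "C2": [-2.0278, -0.5784, 0.0],
    "N3": [-0.957, -1.3998, 0.0],
    "C4": [0.1789, -0.6884, 0.0],
    "C5": [0.3175, 0.6884, 0.0],
    "C6": [-0.8713, 1.437, 0.0],
    "N6": [-0.8975, 2.8259, 0.0],
    "N7": [1.6529, 1.0431, 0.0],
    "C8": [2.3041, -0.1015, 0.0],
    "N9": [1.4537, -1.1742, 0.0]
  }
}
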