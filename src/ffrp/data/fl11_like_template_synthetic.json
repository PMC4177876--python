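{
  "_comment": "Synthetic simplified protein-DNA template: a contact map and residue-base propensity table shaped after the geometry of an Lrp/AsnC-family dimer bound to an A/T-rich duplex. Constructed for this package; NOT extracted from any structure file. Energies are in arbitrary score units; lower is more favourable.",
  "template_id": "fl11_like_2e1c",
  "template_protein_sequence": "MSELDKILEQLRNDPRLTAREIAERLGISENGVQLRSRVKEAIEKLRAEGVIKGTNLGYQILEVKDGKYLVSLLNMSGRLDVAEL",
  "protein_positions": [31, 34, 37, 55, 56, 59, 60, 77, 79],
  "duplex_length": 15,
  "contacts": [
    [31, 4, 1.0],
    [34, 5, 1.0],
    [37, 6, 1.0],
    [55, 7, 1.0],
    [56, 9, 1.0],
    [59, 10, 1.0],
    [60, 11, 1.0],
    [77, 12, 1.0],
    [79, 3, 0.5],
    [79, 13, 0.5]
  ],
  "pair_table": {
    "N": {"A": -1.0, "C": 0.2, "G": 0.1, "T": -0.2},
    "Q": {"A": -0.9, "C": 0.2, "G": 0.0, "T": -0.1},
    "S": {"A": -0.2, "C": 0.1, "G": 0.1, "T": -0.8},
    "T": {"A": -0.7, "C": 0.1, "G": 0.1, "T": -0.3},
    "Y": {"A": -0.1, "C": 0.2, "G": 0.1, "T": -0.9},
    "R": {"A": 0.1, "C": 0.2, "G": -0.6, "T": 0.2},
    "K": {"A": 0.1, "C": 0.1, "G": -0.5, "T": 0.2},
    "E": {"A": 0.2, "C": -0.5, "G": 0.1, "T": 0.2},
    "D": {"A": 0.2, "C": -0.4, "G": 0.1, "T": 0.2},
    "H": {"A": 0.0, "C": 0.0, "G": -0.3, "T": 0.0},
    "W": {"A": -0.2, "C": 0.1, "G": 0.1, "T": -0.2}
  },
  "hydration_table": {
    "A": {"dry": 0.0, "hydrated": 0.10},
    "C": {"dry": 0.0, "hydrated": -0.05},
    "G": {"dry": 0.0, "hydrated": -0.05},
    "T": {"dry": 0.0, "hydrated": 0.10}
  }
}
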