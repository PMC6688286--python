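{
  "comment": "Operational sugar-moiety definitions. Edit thresholds here to swap in an alternative definition; the SMARTS strings document the patterns the procedural detector implements.",
  "circular": {
    "ring_sizes": [5, 6],
    "exocyclic_oxygen_deficit": 2,
    "smarts_documentation": [
      "pyranose-like ring: [C;R1]1[C;R1][C;R1][C;R1][C;R1][O;R1]1 with >= ring_size - exocyclic_oxygen_deficit exocyclic [OX2;!R] substituents on ring carbons",
      "furanose-like ring: [C;R1]1[C;R1][C;R1][C;R1][O;R1]1 with the same exocyclic-oxygen condition"
    ]
  },
  "linear": {
    "min_chain_length": 3,
    "max_chain_length": 7,
    "smarts_documentation": [
      "chain carbon: [C;!R]([#8;!R]) bearing exactly one oxygen substituent; a linear sugar is a maximal component of 3-7 such carbons connected by C-C bonds"
    ]
  },
  "min_aglycone_heavy_atoms": 6
}
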