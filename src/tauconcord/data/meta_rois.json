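{
  "temporal": {
    "name": "temporal",
    "cutoff": 1.36,
    "members": [
      {"region": "entorhinal", "laterality": "bilateral"},
      {"region": "superior_middle_temporal", "laterality": "left"},
      {"region": "medial_temporal_ba37", "laterality": "left"},
      {"region": "inferolateral_temporal", "laterality": "bilateral"}
    ]
  },
  "cortical": {
    "name": "cortical",
    "cutoff": 1.19,
    "members": [
      {"region": "middle_frontal", "laterality": "left"},
      {"region": "superior_middle_temporal", "laterality": "left"},
      {"region": "inferior_parietal", "laterality": "left"},
      {"region": "occipital_ba17_18", "laterality": "left"},
      {"region": "anterior_cingulate", "laterality": "left"},
      {"region": "medial_temporal_ba37", "laterality": "left"},
      {"region": "inferolateral_temporal", "laterality": "bilateral"},
      {"region": "parieto_occipital_ba39", "laterality": "left"},
      {"region": "precuneus_ba7", "laterality": "left"},
      {"region": "frontal_premotor_ba6", "laterality": "left"},
      {"region": "frontal_anterior_ba9", "laterality": "left"},
      {"region": "orbitofrontal_ba11", "laterality": "left"},
      {"region": "primary_motor_ba4", "laterality": "left"}
    ]
  }
}
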