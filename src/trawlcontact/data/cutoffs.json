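{
  "comment": "Maximum length (cm) that can pass through the 115 mm netting of the standard trawl body; classes at or below this length must be excluded before panel-contact inference. 'all' means every size can escape, so contact inference is not applicable. Values from morphology-based mesh-penetration estimates; user-overridable.",
  "cutoffs": [
    {"species": "cod", "max_escape_length": 33, "note": "morphology-based estimate, 115 mm mesh at ~30 deg opening"},
    {"species": "haddock", "max_escape_length": 33, "note": "published haddock morphology data"},
    {"species": "saithe", "max_escape_length": 33, "note": "no morphology data; cod used as proxy"},
    {"species": "nephrops", "max_escape_length": "all", "note": "all sizes can escape 115 mm meshes"},
    {"species": "witch flounder", "max_escape_length": 28, "note": "no morphology data; lemon sole used as proxy"},
    {"species": "lemon sole", "max_escape_length": 28, "note": "unpublished morphology data"}
  ]
}
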