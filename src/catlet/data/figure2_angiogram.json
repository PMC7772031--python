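{
  "schema_version": "1",
  "description": "Worked-example case: total occlusion of the proximal LAD preceded by a significant (non-stenotic) first diagonal. Terminal supplied-segment counts follow the shipped allocation for the average RCA / average LAD / intermediate Dx pattern.",
  "pattern": {
    "rca_type": "average RCA",
    "lad_type": "average",
    "dx_type": "intermediate"
  },
  "vessels": [
    {"id": "5", "name": "Left main", "parent": null},
    {"id": "6", "name": "LAD proximal", "parent": "5"},
    {"id": "7", "name": "LAD mid", "parent": "6"},
    {"id": "8", "name": "LAD apical", "parent": "7", "segments_supplied": 7},
    {"id": "9", "name": "First diagonal", "parent": "6", "segments_supplied": 2},
    {"id": "11", "name": "LCX proximal", "parent": "5"},
    {"id": "13", "name": "LCX distal", "parent": "11", "segments_supplied": 4},
    {"id": "1", "name": "RCA proximal", "parent": null},
    {"id": "2", "name": "RCA mid", "parent": "1"},
    {"id": "3", "name": "RCA distal", "parent": "2"},
    {"id": "4", "name": "Posterior descending artery", "parent": "3", "segments_supplied": 2},
    {"id": "16", "name": "Posterolateral branch from the RCA", "parent": "3", "segments_supplied": 2}
  ],
  "lesions": [
    {
      "node": "6",
      "stenosis_pct": 100.0,
      "occlusion": "chronic_total",
      "in_stent": false,
      "reference_diameter_mm": 3.5,
      "flags": {},
      "culprit": true,
      "preceding_branches": ["9"]
    }
  ]
}
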