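{
  "description": "Lesion-site counts of the reference DLBCL CAR-T cohort: number of patients whose largest lesion of each compartment lies at each anatomic site.",
  "nodal": {
    "n_patients": 124,
    "sites": {
      "abdomen": 58,
      "pelvis": 22,
      "mediastinum": 11,
      "neck": 10,
      "lungs": 7
    }
  },
  "extranodal": {
    "n_patients": 94,
    "sites": {
      "lungs": 34,
      "musculoskeletal": 20,
      "pelvis": 8,
      "liver": 7,
      "spleen": 4
    }
  }
}
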