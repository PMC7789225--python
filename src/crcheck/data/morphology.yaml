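# ICD-O-3 morphology families: the three-digit class subsumes its
# four-digit histology codes (e.g. 807 over 8070/8071).
morphology_families:
  - id: "800"
    label: Neoplasms NOS
    codes: [8000, 8001, 8002, 8003, 8004, 8005]
  - id: "807"
    label: Squamous cell neoplasms
    codes: [8070, 8071, 8072, 8073, 8074, 8075, 8076, 8077, 8078]
  - id: "812"
    label: Transitional cell papillomas and carcinomas
    codes: [8120, 8121, 8122, 8123, 8124, 8130, 8131]
  - id: "814"
    label: Adenomas and adenocarcinomas
    codes: [8140, 8141, 8142, 8143, 8144, 8145, 8146, 8147]
  - id: "816"
    label: Bile duct tumours
    codes: [8160, 8161, 8162]
  - id: "817"
    label: Liver cell tumours
    codes: [8170, 8171, 8172, 8173, 8174, 8175]
  - id: "831"
    label: Renal cell neoplasms
    codes: [8310, 8311, 8312, 8313, 8314, 8315, 8316, 8317, 8318, 8319]
  - id: "855"
    label: Acinar cell neoplasms
    codes: [8550, 8551]
  - id: "872"
    label: Nevi and melanomas
    codes: [8720, 8721, 8722, 8723, 8730]
  - id: "893"
    label: Complex mixed and stromal neoplasms
    codes: [8930, 8931, 8935, 8936]
  - id: "897"
    label: Mixed hepatic tumours
    codes: [8970]
  - id: "906"
    label: Germinomas and seminomas
    codes: [9060, 9061, 9062, 9063, 9064, 9065]
  - id: "938"
    label: Gliomas
    codes: [9380, 9381, 9382, 9383, 9384]
  - id: "971"
    label: Other specified T/NK-cell lymphomas
    codes: [9714, 9716, 9717, 9718, 9719]
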