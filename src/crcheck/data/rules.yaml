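# Exemplar ENCR-style validation rules, one per published rule category.
# severity_note records whether the error/warning level is stated by the
# source recommendation or assumed here.
version: "encr-rules-1.0"

rules:
  - id: R1
    scenario: HARD_DISJOINT
    subject: behaviour
    when:
      behaviour: {in: ["2"]}
      bod: {not_in: ["5", "7"]}
    message: >-
      In-situ behaviour (code 2) requires the basis of diagnosis to be
      cytology (code 5) or histology of the primary tumour (code 7).
    provenance: "ENCR recommendation: basis of diagnosis vs in-situ behaviour"
    severity_note: stated

  - id: R2
    scenario: SOFT_RESTRICTION
    subject: age
    when:
      atoms: [Hepatoblastoma]
    implies:
      age: {max: 5}
    message: Hepatoblastoma is unlikely to occur above the age of 5.
    provenance: "ENCR rule category: unlikely combinations of age and tumour type"
    severity_note: stated

  - id: R3
    scenario: SOFT_RESTRICTION
    subject: age
    when:
      morphology: {in: ["9060-9065", "9070-9072", "9080-9085", "9100-9105"]}
      topography: {in: ["C00-C55", "C57-C61", "C63-C69", "C73-C750",
                        "C754-C768", "C80"]}
      behaviour: {in: ["3"]}
    implies:
      age: {max: 7}
    message: >-
      Malignant extra-cranial/extra-gonadal germ-cell tumour is unlikely
      with age at diagnosis greater than 7.
    provenance: "ENCR rule category: unlikely combinations of age and tumour type"
    severity_note: stated

  - id: R4
    scenario: DEFINED_CODE
    subject: bod
    defines: ENCRBoD_1
    guard: {field: bod, codes: ["1"]}
    definition:
      bod: {in: ["1"]}
      morphology: {in: ["8000", "8720", "9140", "9590", "9800"]}
      behaviour: {not_in: ["2"]}
    message: >-
      Clinical basis of diagnosis (code 1) is valid only for morphologies
      8000, 8720, 9140, 9590 or 9800 with non-in-situ behaviour.
    provenance: "ENCR recommendation: coding of basis of diagnosis"
    severity_note: stated

  - id: R5
    scenario: DEFINED_CODE
    subject: grade
    defines: ENCRGrade_8
    guard: {field: grade, codes: ["8"]}
    definition:
      grade: {in: ["8"]}
      morphology: {in: ["9719", "9727", "9831", "9948"]}
    message: >-
      Grade 8 (NK cell) is valid only with morphologies 9719, 9727, 9831
      or 9948.
    provenance: "ENCR rule category: valid combinations of morphology and grade"
    severity_note: stated

  - id: R6
    scenario: DEFINED_CODE
    subject: morphology
    defines: ENCRMorphTopo_816
    guard: {field: morphology, codes: ["8160", "8161"]}
    definition:
      morphology: {in: ["8160", "8161"]}
      topography: {in: ["C221", "C239", "C240"]}
    message: >-
      Morphologies 8160/8161 (bile-duct tumours) are permitted only on
      topographies C221, C239 or C240.
    provenance: "ENCR rule category: morphology codes and allowed topography codes"
    severity_note: stated

  - id: R7
    scenario: DEFINED_CODE
    subject: bod
    defines: ENCRBoD_2
    guard: {field: bod, codes: ["2"]}
    definition:
      bod: {in: ["2"]}
      morphology: {in: ["9380"]}
      topography: {in: ["C717"]}
    message: >-
      Clinical-investigation basis of diagnosis (code 2) exemplar row:
      valid with morphology 9380 and topography C717.
    provenance: "ENCR rule category: valid combinations of basis-of-diagnosis, morphology and topography"
    severity_note: stated

  - id: R8
    scenario: SOFT_RESTRICTION
    subject: age
    when:
      atoms: [CarcinomaNOSGroupMorphBeh]
    implies:
      age: {min: 6}
    message: >-
      Carcinomas of the NOS group carry an implication for age greater
      than five.
    provenance: "ENCR rule category: unlikely combinations of age and tumour type"
    severity_note: stated

  - id: R9
    scenario: SOFT_RESTRICTION
    subject: sex
    when:
      topography: {in: ["C51-C58"]}
    implies:
      sex: {in: ["2"]}
    message: Female-specific topography (C51-C58) is unlikely with male sex.
    provenance: "ENCR rule category: unlikely sex and topography combinations"
    severity_note: assumed

  - id: R10
    scenario: DEFINED_CODE
    subject: vital_status
    defines: ENCRVitalStatusAlive
    guard: {field: vital_status, codes: ["1"]}
    definition:
      vital_status: {in: ["1"]}
    message: Vital status alive (code 1) exemplar confirmation class.
    provenance: "ENCR call-protocol shape: vital status coding"
    severity_note: assumed

  - id: R11
    scenario: DEFINED_CODE
    subject: extent
    defines: ENCRExtentOfDisease
    guard: {field: extent, codes: ["1", "2", "3"]}
    definition:
      extent: {in: ["1", "2", "3"]}
      behaviour: {in: ["2", "3"]}
    message: >-
      Summary extent of disease applies to in-situ or invasive tumours
      (behaviour 2 or 3).
    provenance: "ENCR rule category: permissible combinations of extent-of-disease and behaviour"
    severity_note: assumed
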