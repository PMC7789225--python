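# ENCR core variable dictionary.
# 55 individual variables, 23 mandatory; the four dates (birth, incidence,
# registration, last known vital status) are split into day/month/year part
# variables sharing a date_group, and the incidence date carries a companion
# precision flag in the same group. Collapsing each date group to one
# logical field leaves 46 logical variables, 17 of them mandatory.
# Code lists beyond those named in the published recommendations are
# provisional completions of the call-protocol shape.
version: "encr-core-1.0"

domains:
  sex:
    "1": Male
    "2": Female
    "3": Other
    "9": Unknown
  behaviour:
    "0": Benign
    "1": Uncertain or unknown whether benign or malignant
    "2": In situ
    "3": Malignant, primary site
  grade:
    "1": Well differentiated
    "2": Moderately differentiated
    "3": Poorly differentiated
    "4": Undifferentiated / anaplastic
    "5": T-cell
    "6": B-cell
    "7": Null cell / non-T-non-B
    "8": NK cell (natural killer cell)
    "9": Grade/differentiation unknown
  basis_of_diagnosis:
    "0": Death certificate only
    "1": Clinical
    "2": Clinical investigation
    "4": Specific tumour markers
    "5": Cytology
    "6": Histology of a metastasis
    "7": Histology of a primary tumour
    "9": Unknown
  vital_status:
    "1": Alive
    "2": Dead
    "3": Lost to follow-up / emigrated
    "9": Unknown
  extent_of_disease:
    "1": Localised
    "2": Regional (advanced)
    "3": Metastatic
    "9": Unknown
  laterality:
    "1": Right
    "2": Left
    "3": One side, unspecified
    "4": Bilateral
    "9": Not applicable / unknown
  yes_no:
    "0": "No"
    "1": "Yes"
    "9": Unknown
  date_flag:
    E: Exact
    A: Approximate
    U: Unknown component(s)
  tnm_edition:
    "5": TNM 5th edition
    "6": TNM 6th edition
    "7": TNM 7th edition
    "8": TNM 8th edition
  icdo_edition:
    "2": ICD-O-2
    "3": ICD-O-3
  stage:
    "0": Stage 0
    "1": Stage I
    "2": Stage II
    "3": Stage III
    "4": Stage IV
    "9": Unknown
  topography:
    pattern: "C[0-9]{3}"
  morphology:
    range: [8000, 9989]
  tnm_t:
    pattern: "[cpy]?T(X|x|0|is|IS|a|A|[1-4][abAB]?)"
  tnm_n:
    pattern: "[cpy]?N[Xx0-3]"
  tnm_m:
    pattern: "[cpy]?M[Xx01]"

variables:
  # identifiers and administration
  - {name: patient_id, mandatory: true, kind: identifier}
  - {name: tumour_id, mandatory: true, kind: identifier}
  - {name: registry_id, mandatory: true, kind: identifier}
  - {name: geo_code, mandatory: true, kind: identifier}
  # demographics
  - {name: sex, mandatory: true, kind: code, domain: sex}
  - {name: age, mandatory: true, kind: integer}
  # dates (each logical date = day/month/year parts in one date group)
  - {name: birth_day, mandatory: true, kind: date_part, date_group: birth, part: day}
  - {name: birth_month, mandatory: true, kind: date_part, date_group: birth, part: month}
  - {name: birth_year, mandatory: true, kind: date_part, date_group: birth, part: year}
  - {name: incidence_day, mandatory: true, kind: date_part, date_group: incidence, part: day}
  - {name: incidence_month, mandatory: true, kind: date_part, date_group: incidence, part: month}
  - {name: incidence_year, mandatory: true, kind: date_part, date_group: incidence, part: year}
  - {name: incidence_flag, mandatory: false, kind: code, domain: date_flag, date_group: incidence}
  - {name: registration_day, mandatory: false, kind: date_part, date_group: registration, part: day}
  - {name: registration_month, mandatory: false, kind: date_part, date_group: registration, part: month}
  - {name: registration_year, mandatory: false, kind: date_part, date_group: registration, part: year}
  - {name: vital_status_day, mandatory: true, kind: date_part, date_group: last_vital_status, part: day}
  - {name: vital_status_month, mandatory: true, kind: date_part, date_group: last_vital_status, part: month}
  - {name: vital_status_year, mandatory: true, kind: date_part, date_group: last_vital_status, part: year}
  # tumour description
  - {name: topography, mandatory: true, kind: code, domain: topography}
  - {name: morphology, mandatory: true, kind: code, domain: morphology}
  - {name: behaviour, mandatory: true, kind: code, domain: behaviour}
  - {name: grade, mandatory: true, kind: code, domain: grade}
  - {name: basis_of_diagnosis, mandatory: true, kind: code, domain: basis_of_diagnosis}
  - {name: icdo_edition, mandatory: true, kind: code, domain: icdo_edition}
  - {name: extent_of_disease, mandatory: false, kind: code, domain: extent_of_disease}
  - {name: laterality, mandatory: false, kind: code, domain: laterality}
  - {name: sequence_number, mandatory: false, kind: integer}
  - {name: tumour_size, mandatory: false, kind: integer}
  - {name: nodes_examined, mandatory: false, kind: integer}
  - {name: nodes_positive, mandatory: false, kind: integer}
  - {name: metastasis_site, mandatory: false, kind: free_text}
  - {name: grade_system, mandatory: false, kind: free_text}
  - {name: morphology_text, mandatory: false, kind: free_text}
  # stage
  - {name: tnm_t_clinical, mandatory: false, kind: code, domain: tnm_t}
  - {name: tnm_n_clinical, mandatory: false, kind: code, domain: tnm_n}
  - {name: tnm_m_clinical, mandatory: false, kind: code, domain: tnm_m}
  - {name: tnm_t_path, mandatory: false, kind: code, domain: tnm_t}
  - {name: tnm_n_path, mandatory: false, kind: code, domain: tnm_n}
  - {name: tnm_m_path, mandatory: false, kind: code, domain: tnm_m}
  - {name: tnm_edition, mandatory: false, kind: code, domain: tnm_edition}
  - {name: stage_group_registry, mandatory: false, kind: code, domain: stage}
  # follow-up
  - {name: vital_status, mandatory: true, kind: code, domain: vital_status}
  - {name: survival_duration, mandatory: true, kind: integer}
  - {name: cause_of_death, mandatory: false, kind: free_text}
  - {name: icd10_code, mandatory: false, kind: free_text}
  - {name: autopsy, mandatory: false, kind: code, domain: yes_no}
  - {name: screening_detected, mandatory: false, kind: code, domain: yes_no}
  # treatment summary
  - {name: surgery, mandatory: false, kind: code, domain: yes_no}
  - {name: radiotherapy, mandatory: false, kind: code, domain: yes_no}
  - {name: chemotherapy, mandatory: false, kind: code, domain: yes_no}
  - {name: immunotherapy, mandatory: false, kind: code, domain: yes_no}
  - {name: hormone_therapy, mandatory: false, kind: code, domain: yes_no}
  - {name: other_treatment, mandatory: false, kind: code, domain: yes_no}
  - {name: comments, mandatory: false, kind: free_text}
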