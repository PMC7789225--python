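# Site and histology group tables for the multiple-primary check.
# Two cases of one patient count as a single primary when their topography
# codes fall in the same site group AND their morphology codes fall in the
# same histology group. Topography entries are three-character site
# prefixes; morphology entries are four-digit code ranges.
mp_topography_groups:
  ENCRTopogTrachea: [C33, C34]
  ENCRTopogColorectal: [C18, C19, C20]
  ENCRTopogUrinary: [C64, C65, C66, C67, C68]
  ENCRTopogSkin: [C44]
  ENCRTopogLiver: [C22]
  ENCRTopogLarynx: [C32]
  ENCRTopogCervixUteri: [C53]
  ENCRTopogCorpusUteri: [C54, C55]
  ENCRTopogBrainCns: [C70, C71, C72]

mp_morphology_groups:
  ENCRMorphSquamous: ["8050-8084", "8120-8131"]
  ENCRMorphAdenomacarcinoma: ["8140-8389", "8480-8560"]
  ENCRMorphMelanoma: ["8720-8790"]
  ENCRMorphStromalSarcoma: ["8930-8936"]
  ENCRMorphEmbryonal: ["8970-8971"]
  ENCRMorphGermCell: ["9060-9105"]
  ENCRMorphGlioma: ["9380-9480"]
  ENCRMorphUnspecified: ["8000-8005"]
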