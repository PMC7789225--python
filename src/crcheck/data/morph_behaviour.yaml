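# Morphology-behaviour classes (Morph-Behaviour entities): the permitted
# morphology x behaviour permutations, grouped into histology families
# following the SEER-style histology/behaviour categorisation.
morph_behaviour_groups:
  - id: CarcinomaNOSGroupMorphBeh
    label: Carcinomas NOS (grouped morphology-behaviour)
  - id: MelanomaGroupMorphBeh
    label: Melanomas
  - id: EmbryonalTumourGroupMorphBeh
    label: Embryonal tumours
  - id: GermCellTumourGroupMorphBeh
    label: Germ-cell tumours
  - id: GliomaGroupMorphBeh
    label: Gliomas
  - id: SarcomaGroupMorphBeh
    label: Sarcomas and stromal tumours
  - id: UnspecifiedNeoplasmGroupMorphBeh
    label: Malignant neoplasms NOS

morph_behaviours:
  - {id: MalignantNeoplasmNOS, morphology: 8000, behaviour: "3",
     parent: UnspecifiedNeoplasmGroupMorphBeh, label: "Neoplasm, malignant"}
  - {id: SquamousCellCarcinomaNOS, morphology: 8070, behaviour: "3",
     parent: CarcinomaNOSGroupMorphBeh, label: "Squamous cell carcinoma, NOS"}
  - {id: SquamousCellCarcinomaKeratinising, morphology: 8071, behaviour: "3",
     parent: CarcinomaNOSGroupMorphBeh,
     label: "Squamous cell carcinoma, keratinising"}
  - {id: SquamousCellCarcinomaInSitu, morphology: 8070, behaviour: "2",
     parent: CarcinomaNOSGroupMorphBeh,
     label: Squamous cell carcinoma in situ}
  - {id: TransitionalCellCarcinoma, morphology: 8120, behaviour: "3",
     parent: CarcinomaNOSGroupMorphBeh, label: Transitional cell carcinoma}
  - {id: AdenocarcinomaNOS, morphology: 8140, behaviour: "3",
     parent: CarcinomaNOSGroupMorphBeh, label: "Adenocarcinoma, NOS"}
  - {id: CholangiocarcinomaMorphBeh, morphology: 8160, behaviour: "3",
     parent: CarcinomaNOSGroupMorphBeh, label: Cholangiocarcinoma}
  - {id: HepatocellularCarcinoma, morphology: 8170, behaviour: "3",
     parent: CarcinomaNOSGroupMorphBeh, label: Hepatocellular carcinoma}
  - {id: RenalCellCarcinoma, morphology: 8312, behaviour: "3",
     parent: CarcinomaNOSGroupMorphBeh, label: Renal cell carcinoma}
  - {id: AcinarCellCarcinoma, morphology: 8550, behaviour: "3",
     parent: CarcinomaNOSGroupMorphBeh, label: Acinar cell carcinoma}
  - {id: MelanomaNOS, morphology: 8720, behaviour: "3",
     parent: MelanomaGroupMorphBeh, label: Malignant melanoma, NOS}
  - {id: EndometrialStromalSarcoma, morphology: 8930, behaviour: "3",
     parent: SarcomaGroupMorphBeh, label: Endometrial stromal sarcoma}
  - {id: StromalSarcomaNOS, morphology: 8936, behaviour: "3",
     parent: SarcomaGroupMorphBeh, label: Gastrointestinal stromal sarcoma}
  - {id: Hepatoblastoma, morphology: 8970, behaviour: "3",
     parent: EmbryonalTumourGroupMorphBeh, label: Hepatoblastoma}
  - {id: Germinoma, morphology: 9064, behaviour: "3",
     parent: GermCellTumourGroupMorphBeh, label: Germinoma}
  - {id: GliomaMalignantNOS, morphology: 9380, behaviour: "3",
     parent: GliomaGroupMorphBeh, label: "Glioma, malignant"}
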