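# ICD-O-3 topography groupings (Topography Grouping entities used by the
# tumour-type classification). Members may be site prefixes (C32 expands to
# C320-C329) or explicit 4-character codes.
topography_groups:
  - id: LarynxTopogGroup
    label: Larynx
    members: [C320, C321, C322, C323, C328, C329]
  - id: UrinaryBladderTopogGroup
    label: Urinary bladder
    members: [C67]
  - id: LungTopogGroup
    label: Trachea, bronchus and lung
    members: [C33, C34]
  - id: LiverTopogGroup
    label: Liver and intrahepatic bile ducts
    members: [C22]
  - id: KidneyTopogGroup
    label: Kidney
    members: [C64]
  - id: SkinTopogGroup
    label: Skin
    members: [C44]
  - id: ColorectalTopogGroup
    label: Colon, rectosigmoid and rectum
    members: [C18, C19, C20]
  - id: BrainCnsTopogGroup
    label: Brain and central nervous system
    members: [C70, C71, C72]
  - id: FemaleGenitalTopogGroup
    label: Female genital organs
    members: [C51, C52, C53, C54, C55, C56, C57, C58]
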