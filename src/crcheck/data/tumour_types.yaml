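# Tumour Type entities: permitted tumour-type classifications from a
# topography grouping combined with a morphology-behaviour class or group.
tumour_types:
  - {id: TumourTypeUrinaryBladder, label: Urinary bladder,
     topography_group: UrinaryBladderTopogGroup,
     morph_behaviour: CarcinomaNOSGroupMorphBeh}
  - {id: TumourTypeLungCarcinoma, label: Trachea bronchus and lung,
     topography_group: LungTopogGroup,
     morph_behaviour: CarcinomaNOSGroupMorphBeh}
  - {id: TumourTypeLarynxCarcinoma, label: Larynx,
     topography_group: LarynxTopogGroup,
     morph_behaviour: CarcinomaNOSGroupMorphBeh}
  - {id: TumourTypeLiverCarcinoma, label: Liver carcinoma,
     topography_group: LiverTopogGroup,
     morph_behaviour: HepatocellularCarcinoma}
  - {id: TumourTypeHepatoblastoma, label: Hepatoblastoma of the liver,
     topography_group: LiverTopogGroup,
     morph_behaviour: Hepatoblastoma}
  - {id: TumourTypeSkinMelanoma, label: Melanoma of skin,
     topography_group: SkinTopogGroup,
     morph_behaviour: MelanomaGroupMorphBeh}
  - {id: TumourTypeRenalCarcinoma, label: Kidney carcinoma,
     topography_group: KidneyTopogGroup,
     morph_behaviour: RenalCellCarcinoma}
  - {id: TumourTypeColorectalCarcinoma, label: Colorectal carcinoma,
     topography_group: ColorectalTopogGroup,
     morph_behaviour: CarcinomaNOSGroupMorphBeh}
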