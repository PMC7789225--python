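# TNM edition 6 topography groupings and stage-group tables.
# Stage rows are evaluated in order; the first matching row wins. "ANY"
# matches every category of the grouping. Stage values are integers 0-4
# with an optional sub-stage suffix (rendered IIIA, IVC, 0a, ...).
# Note the deliberate mismatch with the Topography Grouping entities: the
# ed.6 larynx grouping also covers C101 but not C323/C328/C329.
tnm_groupings:
  - id: TNMEd6Larynx
    label: Larynx (TNM ed.6)
    members: [C320, C321, C322, C101]
    t_categories: [Tis, T1, T1a, T1b, T2, T3, T4a, T4b]
    n_categories: [N0, N1, N2, N3]
    m_categories: [M0, M1]
    stages:
      - {t: [Tis], n: [N0], m: [M0], stage: 0}
      - {m: [M1], stage: 4, sub: C}
      - {t: [T4b], m: [M0], stage: 4, sub: B}
      - {n: [N3], m: [M0], stage: 4, sub: B}
      - {t: [T4a], n: [N0, N1, N2], m: [M0], stage: 4, sub: A}
      - {n: [N2], m: [M0], stage: 4, sub: A}
      - {t: [T1, T1a, T1b], n: [N0], m: [M0], stage: 1}
      - {t: [T2], n: [N0], m: [M0], stage: 2}
      - {t: [T3], n: [N0, N1], m: [M0], stage: 3}
      - {t: [T1, T1a, T1b, T2], n: [N1], m: [M0], stage: 3}

  - id: TNMEd6UrinaryBladder
    label: Urinary bladder (TNM ed.6)
    members: [C67]
    t_categories: [Ta, Tis, T1, T2, T2a, T2b, T3, T3a, T3b, T4a, T4b]
    n_categories: [N0, N1, N2, N3]
    m_categories: [M0, M1]
    stages:
      - {t: [Ta], n: [N0], m: [M0], stage: 0, sub: a}
      - {t: [Tis], n: [N0], m: [M0], stage: 0, sub: is}
      - {m: [M1], stage: 4}
      - {n: [N1, N2, N3], m: [M0], stage: 4}
      - {t: [T4b], n: [N0], m: [M0], stage: 4}
      - {t: [T1], n: [N0], m: [M0], stage: 1}
      - {t: [T2, T2a, T2b], n: [N0], m: [M0], stage: 2}
      - {t: [T3, T3a, T3b, T4a], n: [N0], m: [M0], stage: 3}

  - id: TNMEd6Lung
    label: Trachea, bronchus and lung (TNM ed.6)
    members: [C33, C34]
    t_categories: [Tis, T1, T2, T3, T4]
    n_categories: [N0, N1, N2, N3]
    m_categories: [M0, M1]
    stages:
      - {t: [Tis], n: [N0], m: [M0], stage: 0}
      - {m: [M1], stage: 4}
      - {n: [N3], m: [M0], stage: 3, sub: B}
      - {t: [T4], m: [M0], stage: 3, sub: B}
      - {t: [T1], n: [N0], m: [M0], stage: 1, sub: A}
      - {t: [T2], n: [N0], m: [M0], stage: 1, sub: B}
      - {t: [T1], n: [N1], m: [M0], stage: 2, sub: A}
      - {t: [T2], n: [N1], m: [M0], stage: 2, sub: B}
      - {t: [T3], n: [N0], m: [M0], stage: 2, sub: B}
      - {t: [T3], n: [N1], m: [M0], stage: 3, sub: A}
      - {t: [T1, T2, T3], n: [N2], m: [M0], stage: 3, sub: A}

  - id: TNMEd6Colorectal
    label: Colon and rectum (TNM ed.6)
    members: [C18, C19, C20]
    t_categories: [Tis, T1, T2, T3, T4]
    n_categories: [N0, N1, N2]
    m_categories: [M0, M1]
    stages:
      - {t: [Tis], n: [N0], m: [M0], stage: 0}
      - {m: [M1], stage: 4}
      - {n: [N2], m: [M0], stage: 3, sub: C}
      - {t: [T1, T2], n: [N1], m: [M0], stage: 3, sub: A}
      - {t: [T3, T4], n: [N1], m: [M0], stage: 3, sub: B}
      - {t: [T1, T2], n: [N0], m: [M0], stage: 1}
      - {t: [T3], n: [N0], m: [M0], stage: 2, sub: A}
      - {t: [T4], n: [N0], m: [M0], stage: 2, sub: B}
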