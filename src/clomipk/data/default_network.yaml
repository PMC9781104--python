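compounds:
- id: e_clomiphene
  molecular_weight: 405.96
  fu: 0.1
  kp:
    gut_wall: 8.0
    liver: 15.0
    kidney: 10.0
    rest: 30.0
  salt_factor: 0.6787720706260031
  blood_plasma_ratio: 1.0
  ka: 0.4
  fa: 1.0
  renal_excretion: true
  filtration_scaling: 0.010352545418567465
  is_perpetrator: false
- id: e_4oh_clomiphene
  molecular_weight: 421.96
  fu: 0.15
  kp:
    gut_wall: 6.0
    liver: 12.0
    kidney: 8.0
    rest: 20.0
  salt_factor: 1.0
  blood_plasma_ratio: 1.0
  ka: 0.0
  fa: 1.0
  renal_excretion: true
  filtration_scaling: 0.027030232489895542
  is_perpetrator: false
- id: e_de_clomiphene
  molecular_weight: 377.91
  fu: 0.12
  kp:
    gut_wall: 8.0
    liver: 15.0
    kidney: 10.0
    rest: 28.0
  salt_factor: 1.0
  blood_plasma_ratio: 1.0
  ka: 0.0
  fa: 1.0
  renal_excretion: true
  filtration_scaling: 0.02263493334505982
  is_perpetrator: false
- id: e_4oh_de_clomiphene
  molecular_weight: 393.91
  fu: 0.2
  kp:
    gut_wall: 5.0
    liver: 10.0
    kidney: 7.0
    rest: 15.0
  salt_factor: 1.0
  blood_plasma_ratio: 1.0
  ka: 0.0
  fa: 1.0
  renal_excretion: true
  filtration_scaling: 0.03182515829348231
  is_perpetrator: false
reactions:
- id: parent_4oh_cyp2d6
  substrate: e_clomiphene
  product: e_4oh_clomiphene
  catalyst: CYP2D6
  kcat: null
  km: null
  clint: 2758.819766015373
  cyp2d6_dependent: true
  organs:
  - liver
- id: parent_4oh_cyp2b6
  substrate: e_clomiphene
  product: e_4oh_clomiphene
  catalyst: CYP2B6
  kcat: null
  km: null
  clint: 0.0
  cyp2d6_dependent: false
  organs:
  - liver
- id: parent_de_cyp3a4
  substrate: e_clomiphene
  product: e_de_clomiphene
  catalyst: CYP3A4
  kcat: null
  km: null
  clint: 915.1207028733921
  cyp2d6_dependent: false
  organs:
  - liver
- id: parent_de_cyp2d6
  substrate: e_clomiphene
  product: e_de_clomiphene
  catalyst: CYP2D6
  kcat: null
  km: null
  clint: 228.78017571834798
  cyp2d6_dependent: true
  organs:
  - liver
- id: parent_3oh_cyp2d6
  substrate: e_clomiphene
  product: undefined_metabolite
  catalyst: CYP2D6
  kcat: null
  km: null
  clint: 2826.108052991358
  cyp2d6_dependent: true
  organs:
  - liver
- id: m4oh_dihydroxy_cyp2d6
  substrate: e_4oh_clomiphene
  product: undefined_metabolite
  catalyst: CYP2D6
  kcat: null
  km: null
  clint: 544.0000000000001
  cyp2d6_dependent: true
  organs:
  - liver
- id: m4oh_unspecific
  substrate: e_4oh_clomiphene
  product: undefined_metabolite
  catalyst: unspecific_hepatic
  kcat: null
  km: null
  clint: 120.0
  cyp2d6_dependent: false
  organs:
  - liver
- id: m4oh_de_cyp3a4
  substrate: e_4oh_clomiphene
  product: e_4oh_de_clomiphene
  catalyst: CYP3A4
  kcat: null
  km: null
  clint: 136.00000000000003
  cyp2d6_dependent: false
  organs:
  - liver
- id: de_4ohde_cyp2d6
  substrate: e_de_clomiphene
  product: e_4oh_de_clomiphene
  catalyst: CYP2D6
  kcat: null
  km: null
  clint: 450.0
  cyp2d6_dependent: true
  organs:
  - liver
- id: de_didesethyl_cyp2d6
  substrate: e_de_clomiphene
  product: undefined_metabolite
  catalyst: CYP2D6
  kcat: null
  km: null
  clint: 25.0
  cyp2d6_dependent: true
  organs:
  - liver
- id: de_didesethyl_cyp3a4
  substrate: e_de_clomiphene
  product: undefined_metabolite
  catalyst: CYP3A4
  kcat: null
  km: null
  clint: 25.0
  cyp2d6_dependent: false
  organs:
  - liver
- id: m4ohde_unspecific
  substrate: e_4oh_de_clomiphene
  product: undefined_metabolite
  catalyst: unspecific_hepatic
  kcat: null
  km: null
  clint: 200.0
  cyp2d6_dependent: false
  organs:
  - liver
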