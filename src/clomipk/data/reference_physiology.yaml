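# Reference adult female physiology for the reduced 7-compartment scheme.
# Volumes and blood flows are rounded representative values for a 60 kg
# female adult (ICRP-89-style reference tables); enzyme abundances are
# liver/gut-wall totals of plausible magnitude (they cancel in first-order
# kinetics, where only relative enzyme amounts enter via turnover).
weight: 60.0
height: 163.0
age: 30.0
volumes: # L
  gut_lumen: 1.0
  gut_wall: 1.1
  liver: 1.5
  kidney: 0.31
  rest: 33.0
  arterial: 1.9
  venous: 3.8
blood_flows: # L/h of blood; liver entry is the hepatic artery
  gut_wall: 58.0
  liver: 29.0
  kidney: 62.0
  rest: 151.0
gfr: 6.8 # L/h
enzyme_abundance: # µmol
  - {enzyme: CYP3A4, organ: liver, amount: 2.4}
  - {enzyme: CYP3A4, organ: gut_wall, amount: 0.15}
  - {enzyme: CYP2D6, organ: liver, amount: 0.35}
  - {enzyme: CYP2B6, organ: liver, amount: 0.30}
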