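# Calibration scenario: 1-h [13C]bicarbonate labeling of MGDG moieties in
# intact cells (galactose/glycerol/16:0 turnover as in the bicarbonate MID
# table). Bicarbonate labeling: every analyte carbon is labelable.
# Noiseless by default; set n_ions > 0 for multinomial ion-count noise.
seed: 0
n_ions: 0
p_nat: 0.0107
label_p: 1.0
timepoints: [1.0]
fragments:
  - {name: galactose, n_analyte_carbons: 6, n_labelable: 6}
  - {name: glycerol, n_analyte_carbons: 3, n_labelable: 3}
  - {name: "16:0", n_analyte_carbons: 16, n_labelable: 16}
turnover_rates:
  galactose: 0.092
  glycerol: 0.063
  "16:0": 0.073
pool_contents:
  galactose: 400.92
  glycerol: 400.92
  "16:0": 294.44
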