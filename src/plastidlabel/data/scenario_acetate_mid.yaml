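# Calibration scenario: 1-h [2-13C]acetate labeling of fatty acids in
# isolated plastids (turnover as in the acetate MID table). Acetate labels
# only the even-numbered acyl carbons (N/2 positions).
seed: 0
n_ions: 0
p_nat: 0.0107
label_p: 1.0
timepoints: [1.0]
fragments:
  - {name: "14:0", n_analyte_carbons: 14, n_labelable: 7}
  - {name: "16:0", n_analyte_carbons: 16, n_labelable: 8}
  - {name: "18:0", n_analyte_carbons: 18, n_labelable: 9}
turnover_rates:
  "14:0": 0.023
  "16:0": 0.005
  "18:0": 0.038
pool_contents:
  "14:0": 6.19
  "16:0": 1078.3
  "18:0": 293.2
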