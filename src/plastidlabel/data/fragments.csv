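# Default measured fragments, backbone carbons only (derivatization carbons 0).
# Galactose and glycerol: bicarbonate labeling, every analyte carbon labelable.
# Fatty acids (as FAMEs): [2-13C]acetate labeling, only the N/2 even-numbered
# acyl carbons are labelable.
name,n_analyte_carbons,n_labelable,n_derivatization_carbons
galactose,6,6,0
glycerol,3,3,0
14:0,14,7,0
16:0,16,8,0
18:0,18,9,0
18:1,18,9,0
18:2,18,9,0
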