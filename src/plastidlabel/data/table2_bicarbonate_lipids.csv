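# Printed table: incorporation of [14C]bicarbonate into plastid membrane
# lipids of isolated plastids after 1-h labeling.
# Inputs: incorporation_pmol ([A], pmol 14C/mg chl/h), content_nmol ([B],
# nmol lipid/mg chl), carbon_number (carbons per molecule, C18/C16 species).
# Printed derived cells for diffing: printed_carbon_content ([C], umol C/mg
# chl), printed_specific_radioactivity ([D], x1e-6).
lipid,incorporation_pmol,content_nmol,carbon_number,printed_carbon_content,printed_specific_radioactivity
MGDG,3.58,401,43,17.2,0.208
DGDG,0.50,439,49,21.5,0.023
SQDG,0.24,234,43,10.1,0.023
PG,0.60,159,40,6.36,0.094
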