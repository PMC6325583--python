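# Printed table: incorporation of [13C]bicarbonate into MGDG moieties, for
# intact cells and isolated plastids. Empty cells are "nd" (not detected).
# Inputs: content_nmol ([A], nmol/mg chl), labeled_pct ([B]/[E], % highly
# labeled isotopomers). Printed derived cells for diffing:
# printed_incorporation ([C]/[F], nmol/mg chl/h), printed_turnover
# ([D]/[G], 1/h).
pool,condition,content_nmol,labeled_pct,printed_incorporation,printed_turnover
glycerol,intact_cell,400.92,6.12,24.55,0.063
galactose,intact_cell,400.92,8.80,35.28,0.092
16:0,intact_cell,294.44,7.08,20.85,0.073
18:2,intact_cell,488.41,,,
glycerol,isolated_plastid,400.92,0.55,2.21,0.006
galactose,isolated_plastid,400.92,3.43,13.63,0.035
16:0,isolated_plastid,294.44,,,
18:2,isolated_plastid,488.41,,,
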