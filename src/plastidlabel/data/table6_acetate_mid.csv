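# Printed table: incorporation of [2-13C]acetate into fatty acids of
# isolated plastids. Empty cells are "nd" (not detected).
# Inputs: content_nmol ([A], nmol/mg chl), labeled_pct ([B], % labeled
# isotopomers). Printed derived cells for diffing: printed_incorporation
# ([C], nmol/mg chl/h), printed_turnover ([D], 1/h).
fatty_acid,content_nmol,labeled_pct,printed_incorporation,printed_turnover
14:0,6.19,2.28,0.14,0.023
16:0,1078.3,0.49,5.25,0.005
18:0,293.2,3.72,10.91,0.038
18:1,360.9,,,
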