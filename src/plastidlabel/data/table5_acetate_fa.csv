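# Printed table: incorporation of [2-14C]acetate into fatty acids by
# isolated plastids, 1-h labeling.
# Inputs: incorporation_pmol ([A], pmol 14C/mg chl/h), content_nmol ([B],
# nmol FA/mg chl), c2_units (acetate units per molecule). Printed derived
# cells for diffing: printed_c2_content ([C], nmol C2/mg chl),
# printed_specific_radioactivity ([D], x1e-6).
fatty_acid,incorporation_pmol,content_nmol,c2_units,printed_c2_content,printed_specific_radioactivity
14:0,0.70,6.19,7,43.3,16.2
16:0,5.77,1078,8,8624,0.669
18:0,3.68,293,9,2637,1.396
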