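# Printed cells that cannot be recomputed from the printed inputs of the
# same table (the source presumably carried unrounded intermediates).
# These are expected mismatches: the diff report flags them instead of
# failing.
table,row,column,printed,recomputed,note
2,SQDG,printed_specific_radioactivity,0.023,0.024,0.24/10.06 rounds to 0.024
3,glycerol:intact_cell,printed_incorporation,24.55,24.54,400.92 x 6.12% = 24.536; consistent with unrounded 6.124%
3,galactose:isolated_plastid,printed_incorporation,13.63,13.75,400.92 x 3.43% = 13.752; consistent with unrounded 3.400%
6,16:0,printed_incorporation,5.25,5.28,1078.3 x 0.49% = 5.284; consistent with unrounded 0.487%
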