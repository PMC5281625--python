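analyte	unit	LC	HC
sulfate	mg_per_L	980	121
phosphate	mg_per_L	0.5	0.5
acetate	mg_per_L	330	311
propionate	mg_per_L	30	31
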