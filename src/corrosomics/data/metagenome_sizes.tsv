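sample	total_reads	total_bases
LC3	8800000	2200000000
LC11	8440000	2110000000
HC3	8800000	2200000000
HC11	3016000	754000000
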