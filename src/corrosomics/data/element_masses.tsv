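symbol	monoisotopic_da	standard_atomic_weight
H	1.00782503207	1.008
C	12.0	12.011
N	14.0030740048	14.007
O	15.9949146196	15.999
P	30.97376163	30.973761998
S	31.97207100	32.06
F	18.99840322	18.998403163
Cl	34.96885268	35.45
Br	78.9183371	79.904
I	126.904473	126.90447
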