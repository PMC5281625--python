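gene	family	LC3	LC11	HC3	HC11
total_monooxygenases	monooxygenase	1331.8	1453.0	3.2	7.6
total_dioxygenases	dioxygenase	4262.0	2401.7	572.0	523.6
amoA	nitrogen_cycling	200.5	175.3	0.0	0.0
narB	nitrogen_cycling	0.0	0.0	0.0	10.5
nasA	nitrogen_cycling	17.2	11.7	0.0	0.0
nifH	nitrogen_cycling	116.3	133.6	0.0	0.8
ureC	nitrogen_cycling	9.3	35.8	0.0	0.3
nirS	nitrogen_cycling	4.0	22.3	0.0	0.0
nirK	nitrogen_cycling	26.5	12.3	0.0	0.0
nosZ	nitrogen_cycling	331.5	173.9	1.6	0.0
norB	nitrogen_cycling	506.8	503.7	0.0	1.0
narG	nitrogen_cycling	798.2	709.3	1.6	0.5
napA	nitrogen_cycling	393.6	104.0	0.8	0.0
dsrA	sulfate_reduction	9.6	47.6	0.0	20.1
dsrB	sulfate_reduction	8.2	25.6	8.8	22.2
dsrK	sulfate_reduction	8.2	4.1	132.8	64.7
dsrJ	sulfate_reduction	0.0	0.0	0.0	0.5
dsrP	sulfate_reduction	0.0	0.9	4.8	7.4
dsrM	sulfate_reduction	3.1	0.9	58.4	54.5
dsrE	sulfate_reduction	67.5	56.7	49.6	58.4
dsrF	sulfate_reduction	54.8	72.8	1.6	12.0
dsrH	sulfate_reduction	27.4	36.7	1.6	0.8
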