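name	pathway	substrate	formula	experimental_mass_da	reported_mass_error_mda	reference_rt_min	series	n	high_abundance_sample	abundance_iu
Ethylsuccinic acid	anaerobic	ethane	C6H10O4	146.0579	0.1	1.20	alkylsuccinate	2	HC11	162000
Propylsuccinic acid	anaerobic	propane	C7H12O4	160.0735	0.2	1.67	alkylsuccinate	3	HC11	39000
Butylsuccinic acid	anaerobic	butane	C8H14O4	174.0892	0.3	2.51	alkylsuccinate	4	HC11	11500
Pentylsuccinic acid	anaerobic	pentane	C9H16O4	188.1045	0.3	4.12	alkylsuccinate	5	HC11	42000
Hexylsuccinic acid	anaerobic	hexane	C10H18O4	202.1205	0.4	5.98	alkylsuccinate	6	HC11	15400
Methyl benzylsuccinate	anaerobic	ethylbenzene_or_xylene	C12H14O4	222.0892	0.0	4.60	benzylsuccinate	1	HC11	1080000
Methylbenzylalcohol	aerobic	xylene	C8H10O	122.0732	-0.5	15.17			LC11	175000
Dimethylcatechol	aerobic	ethylbenzene_or_xylene	C8H10O2	138.0681	1.1	5.99			LC11	9000
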