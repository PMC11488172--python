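rt	name	observed_mz	formula	error_ppm	adduct	fragments	source
0.59	Citric acid	191.0197	C6H8O7	-0.1	[M-H]-	128.04	
0.61	Catechin	289.0724	C15H14O6	2.1	[M-H]-	273.08;181.05	
1.11	2,3,6-Trimethylnaphthalene	169.1018	C13H14	3.7	[M-H]-	155.09	
1.43	Protocatechuic acid-O-glucoside	315.0728	C13H16O9	2.2	[M-H]-	195.03;153.02	
2.86	2-Vinyl-1H-indole-3-carboxylic acid	186.06	C11H9NO2	-0.8	[M-H]-	142.07	
4.17	Altechromone A	189.0574	C11H10O3	8.8	[M-H]-	147.04;124.02	
4.30	Tetrahydroxystilbene glucoside	405.1196	C20H22O9	0.5	[M-H]-	243.07;189.06	
5.37	Pseudoginsenoside RT5	699.4336	C36H62O10	1.5	[M+HCOO]-	637.43;491.37	
5.63	Ginsenoside Rf	845.4891	C42H72O14	-1.6	[M+HCOO]-	737.43;635.42;475.38;391.29	
6.17	Epicatechin-3-O-gallate	487.0904	C22H18O10	4.5	[M+HCOO]-	289.07;169.01	
6.32	Emodin 8-O-β-D-glucoside	431.1000	C21H20O10	3.8	[M-H]-	269.05;225.06	
6.83	Ginsenoside Rh7	681.4218	C36H60O9	-0.2	[M+HCOO]-	473.36;619.42	
6.97	Kaempferol	285.0422	C15H10O6	6	[M-H]-	193.01;125.02	
7.20	Ginsenoside Rb1	1153.5986	C54H92O23	-2.9	[M+HCOO]-	945.54;783.49;621.44;459.38	
7.50	Ginsenoside Ro	955.492	C48H76O19	1.3	[M-H]-	793.44;613.37;587.40	
7.59	Ginsenoside Rb2	1123.5877	C53H90O22	-2.5	[M+HCOO]-	945.54;915.53;897.52;783.49;311.10	
7.83	Quercetin	301.0373	C15H10O7	6.5	[M-H]-	285.04;257.05;179.02	
8.09	Ginsenoside Rd	991.5441	C48H82O18	-4.3	[M+HCOO]-	911.54;783.49;621.44;375.29;179.06	
8.56	Chrysophanol	299.0573	C15H10O4	4.1	[M+HCOO]-	225.05	
8.57	Emodin-9-anthrone	255.0675	C15H12O4	4.8	[M-H]-	137.02;109.03	
8.95	Methyl 2-hydroxyhexadecanoate	331.2487	C17H34O3	-1	[M+HCOO]-	255.23;227.24	
9.98	Zingibroside R1	793.4365	C42H66O14	-1.8	[M-H]-	775.43;613.75;595.36;437.34	
10.36	Emodin	269.0477	C15H10O5	8.1	[M-H]-	241.05;225.06	
10.69	20(S)-Ginsenoside Rg3	829.4947	C42H72O13	-1	[M+HCOO]-	605.44;443.39	
12.00	Oleanolic acid-28-O-β--D-glucopyranoside	663.4161	C36H58O8	7.1	[M+HCOO]-	441.34;371.26;351.23	
13.16	Ginsenoside Rg4	811.4827	C42H70O12	-2.7	[M+HCOO]-	603.43;441.37	
13.36	Compound CK	667.4450	C36H62O8	3.6	[M+HCOO]-	621.35;459.38	
14.46	3-Tetradecanone	257.2136	C14H28O	5.4	[M+HCOO]-	197.19	
15.52	Ginsenoside Rh3	649.4357	C36H60O7	5.5	[M+HCOO]-	441.3733	
16.85	Ginsenoside Rh5	697.4523	C37H64O9	5	[M+HCOO]-	490.4017	
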