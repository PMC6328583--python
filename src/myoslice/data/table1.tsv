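function	protein	gene	d8	d14	d24	d35	intercept	slope_x35
Cardiomyocyte contractility	Troponin C1	TNNC1	-1.76	-2.76	-2.26	-2.17	-2.16	-0.13
Cardiomyocyte contractility	Troponin I3	TNNI3	-3.90	-4.48	-3.11	-3.15	-4.51	1.47
Cardiomyocyte contractility	Myosin light chain 2	MYL2	-2.36	-3.93	-2.63	-2.26	-3.29	0.86
Cardiomyocyte contractility	Ryanodine receptor 2	RYR2	-2.57	-1.63	-1.89	-0.73	-2.85	1.98
Cardiomyocyte contractility	Myosin heavy chain 7	MYH7	-3.76	-1.52	-2.64	0.60	-4.46	4.54
Cardiomyocyte contractility	Actin, alpha, cardiac muscle 1	ACTC1	-2.35	-1.44	-1.96	-1.48	-2.22	0.71
Cardiomyocyte contractility	SERCA 2	ATP2A2	-2.08	-0.80	-0.70	-0.86	-1.84	1.27
Cardiomyocyte contractility	Titin	TTN	-0.95	-1.19	-0.52	0.12	-1.55	1.58
Mitochondria	Cytochrome c oxidase subunit 5A	COX5A	-0.97	-2.41	-1.18	-2.25	-1.19	-0.89
Mitochondria	Cytochrome c oxidase subunit 7C	COX7C	-0.99	-2.38	-1.37	-2.11	-1.27	-0.77
Mitochondria	ATP synthase, F1 complex	ATP5C1	-0.91	-2.24	-1.33	-2.12	-1.12	-0.92
Mitochondria	ATP synthase, F0 complex	ATP5H	-0.89	-2.30	-1.04	-2.19	-1.08	-0.91
Mitochondria	NDUFA4, complex associated	NDUFA4	-1.36	-2.39	-1.41	-2.13	-1.58	-0.43
Mitochondria	Ubiquinol-cytochrome c-binding	UQCRB	-1.36	-2.58	-1.51	-2.35	-1.59	-0.63
Mitochondria	Adenine nucleotide translocase 1	SLC25A4	-2.22	-2.68	-2.12	-2.33	-2.42	0.14
Markers of heart failure	Natriuretic peptide B	NPPB	-2.36	-3.50	-3.04	-3.78	-2.38	-1.37
Markers of heart failure	Attractin like 1	ATRNL1	-0.14	-1.23	-0.89	-1.63	-0.11	-1.49
Markers of heart failure	Ribosomal protein S7	RPS7	0.27	-1.11	-0.77	-1.24	0.14	-1.47
Markers of heart failure	Actin, alpha 1, skeletal muscle	ACTA1	-2.78	-3.03	-3.11	-2.75	-2.95	0.06
Markers of heart failure	Msh homeobox 2	MSX2	0.66	-1.09	-0.06	-0.93	0.38	-1.27
Markers of heart failure	Calsequestrin 1	CASQ1	-2.12	-2.71	-1.92	-1.76	-2.60	0.81
Markers of heart failure	X-prolyl aminopeptidase 3	XPNPEP3	-0.80	-1.50	-0.36	-1.21	-0.96	-0.01
Markers of hypertrophy	Ankyrin repeat domain 1	ANKRD1	0.13	-2.87	-1.92	-1.90	-0.73	-1.57
Markers of hypertrophy	Aldolase, fructose-bisphosphate A	ALDOA	-0.96	-0.48	-0.99	-0.94	-0.71	-0.23
Markers of hypertrophy	Crystallin alpha B	CRYAB	-0.31	-2.24	-1.41	-1.97	-0.68	-1.38
Markers of hypertrophy	Cysteine and glycine rich protein 3	CSRP3	1.01	-1.96	-1.42	-2.03	0.60	-2.93
Markers of hypertrophy	FXYD domain containing ion transport regulator 1	FXYD1	-1.69	-1.42	-1.24	-0.92	-1.86	0.94
Markers of hypertrophy	Phosphatidylethanolamine binding protein 1	PEBP1	-1.50	-1.27	-0.99	-1.09	-1.53	0.54
Markers of hypertrophy	Pyruvate dehydrogenase E1 beta	PDHB	-0.96	-1.51	-0.97	-1.33	-1.09	-0.17
Markers of adrenergic activity	Natriuretic peptide A	NPPA	-3.31	-2.88	-3.18	-3.02	-3.20	0.17
Markers of adrenergic activity	Actin, alpha 1, skeletal muscle	ACTA1	-2.78	-3.03	-3.11	-2.75	-2.95	0.06
Markers of adrenergic activity	Lectin serine peptidase 1	MASP1	-2.00	-1.86	-2.44	-1.52	-2.18	0.39
Markers of adrenergic activity	Nuclear receptor subfamily 4A1	NR4A1	-2.51	-2.85	-2.01	-2.77	-2.55	0.02
Markers of adrenergic activity	Fos proto-oncogene	FOS	-1.46	-2.30	-0.70	-2.51	-1.38	-0.63
Markers of adrenergic activity	Inhibitor of DNA binding 1 protein	ID1	-3.03	-2.07	-2.72	-0.99	-3.42	2.10
Markers of adrenergic activity	Kruppel like factor 4	KLF4	-2.05	-2.02	-1.97	-1.70	-2.19	0.43
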