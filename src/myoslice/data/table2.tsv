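function	protein	gene	d8	d14	d24	d35	intercept	slope_x35
Growth factors	Growth differentiation factor 15	GDF15	2.98	2.07	2.26	1.32	3.19	-1.79
Growth factors	Hepatocyte growth factor	HGF	2.21	3.12	2.66	3.17	2.30	0.84
Growth factors	Opioid growth factor rec. like 1	OGFRL1	1.16	2.20	0.91	2.00	1.33	0.41
Growth factors	Platelet derived growth factor receptor beta	PDGFRB	1.34	3.66	1.93	3.56	1.64	1.70
Growth factors	Placental growth factor	PGF	3.06	4.20	2.42	3.65	3.38	-0.08
Growth factors	Transforming growth factor beta 1	TGFB1	1.69	2.75	1.76	2.22	2.04	0.12
Growth factors	Angiotensin I converting enzyme	ACE	1.87	3.02	1.94	2.05	2.43	-0.36
Extracellular matrix	Collagen type I alpha 1 chain	COL1A1	3.16	4.04	2.90	3.86	3.31	0.32
Extracellular matrix	Collagen type I alpha 2 chain	COL1A2	2.42	3.19	2.20	3.36	2.40	0.68
Extracellular matrix	Collagen type III alpha 1 chain	COL3A1	2.25	3.30	2.50	3.52	2.26	1.09
Extracellular matrix	Vimentin	VIM	0.96	1.70	1.25	1.21	1.27	0.02
Extracellular matrix	Laminin subunit gamma 1	LAMC1	0.87	1.45	0.30	1.77	0.73	0.63
Extracellular matrix	Periostin	POSTN	2.70	3.48	1.92	3.44	2.73	0.26
Extracellular matrix	Fibronectin 1	FN1	3.24	3.89	2.41	3.35	3.49	-0.46
Hypoxia-induced targets	Vascular endothelial growth factor A	VEGFA	-0.59	1.18	-0.98	-0.38	0.26	-0.78
Hypoxia-induced targets	Solute carrier family 2 member 1	SLC2A1	-1.97	1.79	-1.30	-0.12	-0.70	0.53
Hypoxia-induced targets	Glyceraldehyde-3-phosphate dehydrogenase	GAPDH	-0.20	-0.19	-0.24	-1.02	0.18	-1.02
Hypoxia-induced targets	Protein kinase, cAMP-activated	PRKACA	-0.33	-0.78	-1.11	-0.62	-0.50	-0.37
Hypoxia-induced targets	Phosphoglycerate kinase 1	PGK1	-0.85	0.18	-0.80	-0.94	-0.24	-0.63
Positive trend	Elastin	ELN	-2.68	-1.10	-0.75	2.12	-3.88	5.67
Positive trend	Nerve growth factor receptor	NGFR	-1.80	2.04	0.91	3.71	-2.03	5.61
Positive trend	Kelch-like family member 38	KLHL38	-3.53	-0.90	-1.16	1.48	-4.22	5.52
Positive trend	X-prolyl aminopeptidase 2	XPNPEP2	-1.77	2.22	1.05	3.65	-1.87	5.45
Positive trend	Integrin subunit beta like 1	ITGBL1	-2.75	0.02	-0.20	2.16	-3.30	5.38
Positive trend	Neurotrophic receptor tyrosine kinase 2	NTRK2	-1.88	-0.43	-0.61	2.45	-2.98	4.95
Positive trend	Phospholipid phosphatase rel. 4	LPPR4	-0.39	0.67	2.76	2.60	-0.96	4.10
Negative trend	Prolyl 4-hydroxylase alpha 3	P4HA3	3.61	4.06	2.55	0.40	5.26	-4.51
Negative trend	Interleukin 6	IL6	2.56	1.20	1.13	-1.18	3.43	-4.33
Negative trend	TNF receptor superfamily member 12 A	TNFRSF12A	2.71	-1.30	-0.96	-1.48	2.18	-4.21
Negative trend	Cell division cycle associated 2	CDCA2	1.94	0.23	-0.48	-1.50	2.41	-4.08
Negative trend	Wnt family member 5 A	WNT5A	2.90	1.19	0.20	-0.21	3.20	-3.77
Negative trend	Protein phosphatase 1 regulatory subunit 16 B	PPP1R16B	0.21	-0.31	-2.56	-2.36	0.91	-3.75
Negative trend	C-X-C motif chemokine ligand 1	CXCL1	3.15	1.10	0.25	0.02	3.26	-3.68
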