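gene	group	HER2	LUM	TN	Blood	BM	Breast	Colon	Heart	Kidney	Liver	Lung	Pancreas	Skin	Stomach
ADAM12	mesenchymal	9.48	9.61	9.09	5.99	4.87	8.58	5.19	5.99	6.03	5.29	6.14	7.02	6.27	6.41
CDH11	mesenchymal	9.96	10.16	9.52	4.37	4.88	9.19	7.64	8.34	8.40	6.10	10.08	8.55	8.63	9.45
F2RL2	mesenchymal	7.57	8.06	6.88	4.88	4.23	7.08	5.34	6.11	5.11	6.56	4.97	6.92	6.43	7.55
FAP	mesenchymal	10.07	10.09	9.53	3.97	3.30	8.58	3.93	5.65	4.71	4.47	7.32	8.09	8.04	5.64
CDH1	epithelial	10.82	10.41	9.92	4.81	7.44	9.44	11.19	4.07	9.40	10.07	9.46	10.12	10.25	9.29
CDH3	epithelial	9.92	8.40	10.28	3.61	3.49	9.52	4.40	4.20	7.54	3.96	6.86	5.93	9.61	5.13
EPHB3	epithelial	8.56	8.51	9.26	6.02	6.10	8.67	8.21	6.57	6.99	6.51	7.29	8.12	8.90	9.70
ERBB2	epithelial	12.84	9.57	8.51	6.15	5.48	8.20	8.71	8.74	8.90	7.63	8.36	7.69	8.67	8.56
ERBB3	epithelial	10.78	11.37	10.15	5.53	5.27	10.08	11.47	7.96	10.50	10.58	10.06	9.60	10.52	10.64
IGSF9	epithelial	9.30	8.47	8.63	4.54	4.52	6.32	9.17	5.65	5.16	7.19	4.75	5.59	8.07	6.83
ITGB6	epithelial	9.88	8.22	7.92	3.30	3.35	7.86	8.16	5.67	8.22	4.24	9.15	7.62	6.40	6.74
MUC1	epithelial	11.02	11.86	9.87	5.80	7.29	9.62	10.85	6.32	10.66	5.71	12.04	10.52	8.38	12.19
MUC16	epithelial	4.48	3.94	6.76	2.62	2.77	4.48	2.59	3.95	2.50	2.54	3.89	2.81	3.56	4.23
PVRL4	epithelial	9.23	8.49	8.73	5.59	5.96	7.48	6.09	6.48	6.49	5.50	6.65	6.58	8.88	6.82
TLCD1	epithelial	9.11	8.36	8.21	4.66	5.47	6.56	8.26	6.70	8.10	7.44	7.52	6.99	8.80	7.03
BAMBI	other	10.88	10.56	10.77	6.67	8.07	10.18	8.89	10.02	10.24	9.72	9.58	8.95	8.35	8.34
BMPR1B	other	6.69	9.32	6.89	4.29	4.82	6.73	5.19	7.44	8.37	6.31	7.11	7.31	6.55	8.25
CA12	other	9.30	11.86	8.27	5.74	5.77	9.86	12.59	6.95	12.82	6.08	7.81	9.73	11.53	8.93
CLSTN2	other	6.11	8.84	5.62	3.67	4.67	8.13	4.70	7.43	7.08	5.32	5.44	6.16	6.35	6.98
CT83	other	5.21	4.40	7.66	4.31	4.37	4.60	4.32	5.42	4.57	4.33	4.34	4.83	4.16	5.49
FPR3	other	8.92	8.37	8.93	6.01	5.43	7.51	7.50	7.57	6.76	7.88	8.56	7.90	7.23	7.53
FZD7	other	9.05	9.41	10.48	4.68	5.86	11.37	8.39	9.40	8.93	6.58	9.10	8.48	10.21	9.76
GABRP	other	7.64	7.39	11.53	3.26	3.08	11.48	4.27	5.29	6.34	6.07	4.79	6.06	8.21	6.96
GPNMB	other	13.19	12.82	13.15	6.09	7.79	13.19	10.74	13.08	10.80	10.44	12.57	11.67	13.92	11.59
GPR19	other	6.32	5.57	7.08	6.94	5.50	4.78	4.65	4.83	4.14	4.52	4.26	6.08	4.41	5.60
GRIA2	other	3.10	5.71	3.66	2.07	2.47	5.21	2.17	2.94	3.47	3.04	2.39	5.36	4.91	5.66
KCNS3	other	9.85	9.68	9.12	3.91	5.08	9.37	8.63	7.91	8.11	7.77	10.47	8.80	8.89	9.38
KIAA1324	other	10.06	10.67	8.48	8.79	5.85	10.00	9.46	5.68	4.62	5.11	7.65	10.56	7.74	10.03
LAMP5	other	7.98	8.69	7.10	6.99	6.96	6.23	5.08	5.33	5.87	5.62	6.03	7.27	5.66	6.36
LDLRAD3	other	10.07	10.70	10.46	8.71	7.71	10.49	7.06	8.07	7.77	7.80	8.20	9.13	10.75	8.77
LRP8	other	8.30	7.27	8.67	7.47	7.90	6.42	6.36	7.00	6.34	5.58	7.14	6.90	6.96	7.25
MMP14	other	8.88	8.74	8.69	5.47	5.43	7.17	6.74	7.39	7.27	6.33	7.50	7.46	7.85	8.45
NKAIN1	other	6.02	7.95	5.88	4.30	4.67	5.31	4.95	5.17	4.96	5.43	4.79	5.86	6.04	6.59
NPY1R	other	6.76	10.95	8.55	3.26	4.36	11.73	9.39	7.16	11.49	10.01	8.11	10.25	10.98	8.36
PMEPA1	other	10.88	10.43	10.45	6.80	5.98	10.24	8.87	9.58	8.81	7.12	9.46	9.98	9.35	9.29
PRLR	other	8.30	8.61	7.42	5.15	5.65	7.19	6.61	6.31	7.77	7.21	5.37	6.85	6.12	7.17
PROM1	other	10.01	7.94	11.23	4.88	8.04	10.08	11.50	8.46	10.71	7.33	7.89	9.85	7.61	10.59
PTPRT	other	5.13	7.53	4.78	4.43	4.40	6.72	4.94	5.83	5.51	5.21	5.51	6.10	4.99	6.20
SDC1	other	12.12	11.00	11.26	6.02	7.10	9.51	10.82	5.30	11.26	12.33	10.88	9.36	12.43	9.96
SLC16A6	other	8.60	9.74	7.56	9.90	8.65	7.51	6.15	6.70	6.65	7.04	8.22	7.27	8.54	7.48
SLC2A10	other	11.00	11.01	9.30	2.71	5.83	10.09	9.78	7.05	7.78	10.88	9.40	9.72	8.71	9.59
SLC39A6	other	10.16	12.20	9.96	8.24	8.58	10.73	8.08	8.89	9.49	8.26	9.12	9.76	10.00	9.19
SLC4A11	other	8.66	7.42	8.04	5.87	5.74	7.48	5.96	7.00	8.37	6.09	6.52	6.66	7.86	7.49
TPBG	other	11.59	12.31	11.17	6.56	7.08	11.44	10.21	9.45	9.59	7.91	9.84	10.21	10.90	10.71
TREM2	other	8.37	8.53	8.12	4.32	4.20	7.06	5.47	6.29	4.39	4.62	8.36	6.13	4.98	5.49
TRPV6	other	8.68	6.09	7.25	5.07	4.68	6.20	4.70	5.76	6.30	6.00	4.20	7.94	6.92	7.50
TTYH1	other	4.77	4.29	6.30	3.59	3.80	5.87	3.78	4.99	3.54	4.55	3.00	5.70	4.70	4.94
UNC5A	other	6.50	5.81	4.28	3.67	3.64	4.41	2.97	4.75	3.41	3.55	3.54	4.34	2.70	5.45
VANGL2	other	8.31	8.36	9.37	5.39	5.58	8.24	7.40	7.58	7.72	6.58	7.70	7.72	9.76	8.73
VTCN1	other	8.92	9.44	10.10	4.19	4.64	10.30	4.12	5.52	8.47	5.76	5.19	8.35	7.00	6.34
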