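gene	group	HER2	LUM	TN	Blood	BM	Breast	Colon	Heart	Kidney	Liver	Lung	Pancreas	Skin	Stomach
COL11A1	mesenchymal	10.88	10.64	10.42	3.21	3.75	5.86	3.62	3.50	4.24	3.79	4.35	6.02	7.10	4.19
COL12A1	mesenchymal	10.24	10.27	9.53	3.75	4.43	8.41	6.28	8.10	7.37	6.23	7.79	7.95	9.22	8.49
COL1A1	mesenchymal	14.13	14.02	13.23	4.70	7.43	11.35	9.49	10.56	9.22	9.43	10.67	11.45	12.90	12.30
COL1A2	mesenchymal	14.62	14.72	14.20	5.35	7.12	13.50	10.95	11.78	10.46	10.06	12.61	12.69	13.79	12.90
COL3A1	mesenchymal	14.49	14.60	14.17	3.82	5.87	13.80	12.26	12.20	11.25	11.81	12.51	13.08	13.73	13.73
COL5A1	mesenchymal	11.45	11.30	10.64	4.47	5.76	9.70	8.25	9.16	7.51	8.12	9.30	9.25	10.43	10.64
COL5A2	mesenchymal	12.45	12.36	11.79	4.84	5.16	10.95	8.75	9.59	8.39	8.97	9.95	10.21	10.87	10.86
COL6A3	mesenchymal	13.84	14.00	13.31	6.30	6.87	13.67	10.57	12.48	9.84	10.28	12.86	12.60	12.99	13.05
COL8A1	mesenchymal	9.13	9.28	8.64	4.23	4.51	7.98	5.37	8.18	6.95	5.73	9.08	7.42	6.69	7.45
FN1	mesenchymal	12.77	12.56	12.03	4.64	4.97	9.64	8.50	10.24	8.54	12.59	12.24	9.51	9.79	10.30
INHBA	mesenchymal	9.58	9.44	9.35	3.71	8.08	6.07	3.51	6.54	5.12	7.59	8.45	7.13	6.21	5.65
POSTN	mesenchymal	13.62	13.89	13.19	3.63	4.43	12.11	10.54	10.00	9.43	8.16	11.25	9.71	12.79	12.30
THBS2	mesenchymal	12.83	12.69	12.18	5.69	5.51	12.04	6.24	10.50	9.03	9.83	9.59	10.62	12.64	9.76
AZGP1	epithelial	12.94	13.21	11.30	3.78	4.29	13.16	6.83	10.05	11.65	13.70	8.30	11.15	12.58	10.21
AEBP1	other	12.54	12.35	11.43	6.94	7.42	10.92	7.88	9.01	9.56	9.09	10.53	9.53	11.08	10.37
AGR3	other	7.34	12.61	5.33	2.93	3.48	8.98	13.24	3.66	5.31	3.27	12.27	9.55	6.70	8.04
ASPN	other	10.83	11.50	10.08	4.50	4.40	10.01	7.68	10.56	8.87	10.00	9.64	10.44	9.68	10.32
BRINP3	other	6.87	3.53	3.93	2.73	2.68	3.28	7.45	4.48	5.10	2.80	5.18	4.38	3.14	3.67
CHI3L1	other	10.08	9.34	11.62	11.32	12.17	9.56	5.08	6.33	9.29	10.02	9.26	7.51	11.12	6.59
CILP	other	10.66	11.34	9.70	6.38	6.03	11.10	7.36	10.11	7.52	7.58	7.62	9.18	10.87	9.55
COL10A1	other	11.07	11.20	10.07	5.97	6.17	6.27	5.31	5.88	5.93	6.41	6.54	8.05	5.89	6.43
COMP	other	9.79	9.88	8.63	4.41	3.88	5.72	3.83	5.49	4.73	3.86	5.81	6.26	8.63	5.21
CST1	other	7.39	7.32	6.40	3.60	3.55	3.55	3.75	4.09	3.08	3.61	3.61	4.58	4.32	3.89
CTHRC1	other	13.16	13.07	13.08	4.20	6.55	11.38	7.23	8.30	7.44	6.27	9.32	10.62	11.55	8.99
CXCL10	other	11.36	10.12	11.78	7.11	6.55	7.98	8.04	8.00	8.31	9.89	9.49	8.45	7.15	8.77
CXCL11	other	9.11	7.87	9.27	3.91	4.16	5.54	5.71	4.94	5.48	6.22	7.38	8.09	5.11	6.43
CXCL13	other	9.53	8.19	9.71	3.20	3.35	4.86	8.48	4.01	3.56	5.90	6.00	5.79	3.85	8.85
CXCL9	other	11.39	10.06	11.32	6.16	6.06	8.64	8.14	7.90	8.15	9.88	9.57	8.56	7.75	8.45
EPYC	other	6.77	6.18	6.09	2.66	3.52	4.00	3.03	4.56	3.60	3.03	3.31	4.77	2.89	4.51
FDCSP	other	6.98	6.60	10.32	3.55	3.62	8.41	7.91	4.03	3.45	4.48	4.60	6.05	4.52	7.47
GRP	other	7.84	8.71	6.83	3.99	3.75	7.56	4.12	4.72	4.48	4.73	7.45	6.24	5.21	8.28
IBSP	other	6.99	6.14	6.51	4.08	4.28	3.24	3.44	5.31	3.87	4.55	3.30	4.38	3.47	5.28
IL4I1	other	7.73	6.96	8.15	5.74	4.67	4.95	5.40	5.64	5.07	5.53	5.76	6.08	5.69	6.03
LUM	other	13.80	13.80	13.18	2.68	5.20	13.63	11.24	12.48	12.00	10.27	13.66	13.24	12.28	12.88
MATN3	other	6.57	7.82	6.11	2.55	2.86	5.58	3.58	3.10	5.32	2.94	7.43	5.53	5.45	3.80
MDK	other	10.07	9.55	9.43	4.86	5.96	8.09	8.14	6.22	6.60	6.17	7.93	8.07	6.32	8.20
MFAP2	other	9.47	9.69	10.09	2.32	3.64	7.71	4.64	5.35	4.98	4.77	9.13	8.58	8.99	7.80
MGP	other	13.36	14.17	13.82	4.21	4.95	14.48	8.78	13.63	13.00	8.76	13.64	13.16	12.22	13.34
MMP1	other	9.46	7.05	9.60	4.14	3.30	3.49	7.23	4.37	5.63	3.50	6.09	8.79	4.57	8.50
MMP11	other	9.60	9.49	8.85	5.10	5.33	6.00	5.93	7.55	6.61	5.37	5.46	7.09	5.67	7.84
MMP12	other	8.24	7.10	9.63	4.31	4.98	6.60	10.16	6.46	6.35	4.99	6.62	7.94	6.27	7.96
MMP13	other	8.32	7.67	7.48	3.74	4.41	4.01	3.47	4.38	3.65	4.39	3.70	4.47	3.77	4.82
MMP3	other	9.01	8.72	8.82	4.64	4.89	7.30	6.47	6.05	5.01	4.95	4.47	6.13	6.06	7.91
MMP7	other	9.04	9.02	11.65	4.09	4.86	10.94	5.84	6.79	11.22	7.51	9.23	11.38	9.29	9.07
MUCL1	other	13.93	10.70	8.81	3.84	4.48	13.03	4.57	5.79	5.07	4.67	5.25	5.35	13.44	6.28
MXRA5	other	12.84	12.69	12.28	4.13	5.90	11.95	9.47	9.94	9.54	9.41	9.68	10.53	12.17	11.36
SCUBE2	other	8.39	11.43	7.35	4.47	3.90	10.78	8.03	6.98	5.44	5.97	7.77	8.41	9.14	9.07
SFRP4	other	9.63	10.06	9.14	4.87	5.38	10.51	5.37	7.66	6.96	5.69	8.34	9.12	7.13	8.30
STC2	other	7.87	10.45	8.27	4.36	4.86	10.36	4.75	7.48	7.17	5.14	7.12	8.45	6.33	6.66
ZG16B	other	9.87	10.73	8.26	7.03	7.88	9.00	9.62	4.58	3.81	4.87	5.75	6.31	9.87	9.21
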