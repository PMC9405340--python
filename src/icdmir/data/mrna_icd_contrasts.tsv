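feature_id	fc_Mino_gIrr	fc_Mino_DXR	fc_Mino_RA_IFNa	fc_MDA_gIrr	fc_MDA_DXR	fc_MDA_RA_IFNa	p_Mino_gIrr	p_Mino_DXR	p_Mino_RA_IFNa	p_MDA_gIrr	p_MDA_DXR	p_MDA_RA_IFNa
DPYSL2	1.10	−1.69	−1.89	−1.01	−3.84	−2.84	1.00	1.81 × 10^−2	3.63 × 10^−3	1.00	2.91 × 10^−14	2.00 × 10^−8
ENC1	1.14	−1.52	−2.35	−1.04	−1.46	−1.53	1.00	1.61 × 10^−2	7.31 × 10^−8	1.00	4.42 × 10^−3	2.09 × 10^−3
MEGF9	−1.36	−1.36	−1.33	−1.04	−1.80	−1.50	1.78 × 10^−1	1.74 × 10^−2	2.70 × 10^−2	1.00	1.48 × 10^−10	7.77 × 10^−5
NIN	−1.12	−1.42	−1.38	1.05	−1.55	−1.74	1.00	4.30 × 10^−3	8.08 × 10^−3	1.00	1.66 × 10^−5	7.53 × 10^−8
PPM1F	1.15	−1.44	−1.42	−1.02	−1.86	−1.48	1.00	1.56 × 10^−2	2.28 × 10^−2	1.00	7.03 × 10^−8	3.48 × 10^−3
TTC3	−1.05	−1.49	−1.39	1.02	−1.50	−1.65	1.00	1.22 × 10^−2	4.92 × 10^−2	1.00	4.65 × 10^−3	5.93 × 10^−4
ADM	−1.05	1.35	1.40	−1.02	2.68	2.02	1.00	2.70 × 10^−2	1.47 × 10^−2	1.00	4.98 × 10^−29	9.12 × 10^−14
ANKRD33B	−1.02	1.34	1.49	1.15	2.45	1.67	1.00	2.54 × 10^−2	1.29 × 10^−3	1.00	3.86 × 10^−16	4.89 × 10^−5
CEACAM1	−2.06	4.19	6.52	2.92	9.15	26.13	NS	4.04 × 10^−3	2.62 × 10^−5	1.00	6.84 × 10^−3	3.32 × 10^−5
DDX58	1.02	9.96	10.85	1.05	2.66	6.46	1.00	2.96 × 10^−6	1.49 × 10^−7	1.00	3.94 × 10^−2	2.13 × 10^−5
HERC5	−1.45	149.92	213.69	1.06	3.60	5.23	1.00	1.61 × 10^−5	3.92 × 10^−7	1.00	8.48 × 10^−3	7.83 × 10^−4
HLA-B	1.03	2.12	2.47	1.04	1.60	2.95	1.00	2.98 × 10^−4	9.62 × 10^−7	1.00	1.50 × 10^−2	5.89 × 10^−10
HLA-E	1.04	2.61	2.52	1.04	2.32	2.21	1.00	2.62 × 10^−3	2.66 × 10^−3	1.00	2.84 × 10^−3	1.10 × 10^−2
IFI27L1	1.11	1.42	1.58	−1.07	1.42	1.40	1.00	3.11 × 10^−2	2.98 × 10^−3	1.00	5.86 × 10^−3	2.19 × 10^−2
IFI44	−1.61	39.21	3133.84	1.09	5.48	18.69	1.00	7.36 × 10^−3	6.20 × 10^−13	1.00	2.05 × 10^−2	2.54 × 10^−5
IFI6	1.25	66.39	135.73	1.12	7.39	112.41	1.00	2.86 × 10^−9	2.19 × 10^−14	1.00	1.47 × 10^−3	2.61 × 10^−16
IFIH1	−1.11	6.94	11.16	1.06	3.06	15.55	1.00	2.04 × 10^−5	2.76 × 10^−9	1.00	9.59 × 10^−3	1.31 × 10^−12
IFIT1	−1.60	374.39	2665.15	1.03	5.84	27.03	1.00	2.96 × 10^−6	2.60 × 10^−12	1.00	1.74 × 10^−2	1.90 × 10^−6
IFIT2	1.07	99.54	140.41	1.02	7.65	5.51	1.00	6.41 × 10^−7	4.33 × 10^−9	1.00	3.48 × 10^−3	3.48 × 10^−2
IFIT3	−1.02	21.47	81.05	−1.04	4.85	10.30	1.00	2.45 × 10^−7	8.54 × 10^−17	1.00	2.30 × 10^−3	4.08 × 10^−6
ISG15	1.15	11.46	29.74	1.09	2.62	12.29	1.00	2.53 × 10^−7	5.05 × 10^−16	1.00	4.01 × 10^−2	1.02 × 10^−9
ISG20	−1.24	7.94	14.92	1.36	6.74	16.63	1.00	3.36 × 10^−5	9.48 × 10^−10	1.00	6.96 × 10^−5	1.79 × 10^−9
MDK	1.02	5.67	5.04	1.03	2.83	2.92	1.00	1.03 × 10^−3	1.33 × 10^−3	1.00	2.44 × 10^−2	3.82 × 10^−2
MX2	1.00	3.66	6.58	−1.27	2.30	40.51	1.00	1.99 × 10^−5	1.26 × 10^−12	1.00	7.06 × 10^−3	1.79 × 10^−45
OASL	−1.50	426.45	710.61	−1.04	11.42	10.78	1.00	9.62 × 10^−7	5.52 × 10^−9	1.00	1.86 × 10^−4	6.20 × 10^−4
PELI1	1.04	1.38	1.43	−1.05	1.63	1.47	1.00	1.23 × 10^−2	4.10 × 10^−3	1.00	4.44 × 10^−4	2.15 × 10^−2
PIM2	−1.05	1.34	1.56	−1.01	1.67	2.39	1.00	2.63 × 10^−2	2.73 × 10^−4	1.00	5.06 × 10^−5	6.56 × 10^−13
PLEKHA4	−1.34	14.67	51.65	−1.23	3.87	3.33	NS	2.57 × 10^−2	1.42 × 10^−4	1.00	1.86 × 10^−10	9.16 × 10^−8
PNPLA2	−1.10	1.55	1.62	−1.01	1.56	1.49	1.00	1.73 × 10^−2	4.45 × 10^−3	1.00	1.09 × 10^−10	9.63 × 10^−8
PSMB9	1.07	1.91	3.05	1.10	1.55	2.36	1.00	1.39 × 10^−3	2.48 × 10^−11	1.00	1.12 × 10^−2	6.13 × 10^−8
RNF114	1.18	1.53	1.31	1.01	1.45	1.49	1.00	5.61 × 10^−4	3.88 × 10^−2	1.00	2.04 × 10^−4	1.56 × 10^−4
RSAD2	−3.26	41.51	214.37	−2.47	18.77	491.58	NaN	5.07 × 10^−3	4.02 × 10^−6	1.00	1.84 × 10^−2	2.40 × 10^−8
RTP4	−1.23	4.07	4.89	−1.12	8.17	43.22	NaN	4.34 × 10^−3	5.59 × 10^−4	1.00	1.66 × 10^−3	1.02 × 10^−9
SAMD9	−1.14	8.24	6.89	−1.09	3.14	6.83	1.00	3.60 × 10^−5	6.22 × 10^−5	1.00	2.01 × 10^−2	4.13 × 10^−5
SCAMP1-AS1	1.03	2.26	2.30	1.01	2.04	3.42	NS	2.12 × 10^−2	2.40 × 10^−2	1.00	4.89 × 10^−2	2.82 × 10^−4
SRGN	−1.08	1.77	1.71	−1.03	1.54	1.66	1.00	6.71 × 10^−3	1.07 × 10^−2	1.00	2.87 × 10^−2	1.60 × 10^−2
ST3GAL1	−1.08	1.40	1.51	1.07	1.40	1.53	1.00	4.71 × 10^−3	1.67 × 10^−4	1.00	8.86 × 10^−4	4.33 × 10^−5
TAP1	1.04	3.09	4.10	1.05	2.12	3.53	1.00	2.05 × 10^−5	2.42 × 10^−9	1.00	1.99 × 10^−3	5.53 × 10^−8
TAP2	−1.24	1.34	2.30	−1.01	1.93	1.46	9.03 × 10^−1	2.55 × 10^−2	3.75 × 10^−15	1.00	3.22 × 10^−14	1.60 × 10^−4
ZNF600	1.07	1.84	1.55	−1.00	1.76	1.56	1.00	4.32 × 10^−3	5.28 × 10^−2	1.00	1.92 × 10^−3	4.58 × 10^−2
ZNFX1	−1.04	2.05	2.84	−1.01	1.56	2.91	1.00	2.34 × 10^−3	3.73 × 10^−7	1.00	4.48 × 10^−2	4.86 × 10^−8
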