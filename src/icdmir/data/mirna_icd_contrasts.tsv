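feature_id	accession	fc_Mino_gIrr	fc_Mino_DXR	fc_Mino_RA_IFNa	fc_MDA_gIrr	fc_MDA_DXR	fc_MDA_RA_IFNa	p_Mino_gIrr	p_Mino_DXR	p_Mino_RA_IFNa	p_MDA_gIrr	p_MDA_DXR	p_MDA_RA_IFNa
hsa-let-7b-3p	MIMAT0004482	NS	−2.37	−3.26	NS	−1.97	−1.68	NS	1.20 × 10^−70	1.07 × 10^−137	NS	7.71 × 10^−58	1.14 × 10^−34
hsa-let-7f-2-3p	MIMAT0004487	NS	−1.66	−3.71	NS	−1.42	−1.45	NS	3.93 × 10^−43	1.10 × 10^−233	NS	1.56 × 10^−24	5.83 × 10^−26
hsa-miR-576-3p	MIMAT0004796	NS	−1.44	−1.89	NS	−1.38	−1.38	NS	4.30 × 10^−2	4.28 × 10^−5	NS	2.41 × 10^−2	2.77 × 10^−2
hsa-miR-98-3p	MIMAT0022842	−1.25	−1.47	−22.34	NS	−1.34	−2.29	1.08 × 10^−4	1.67 × 10^−14	1.00 × 10^−169	NS	6.61 × 10^−17	1.04 × 10^−102
hsa-miR-30c-1-3p	MIMAT0004674	−1.15	−2.20	−2.40	NS	−1.60	−1.79	1.36 × 10^−2	5.77 × 10^−60	8.42 × 10^−85	NS	4.11 × 10^−23	5.49 × 10^−32
hsa-miR-181a-3p	MIMAT0000270	−1.14	−2.46	−3.71	NS	−1.78	−1.52	6.43 × 10^−18	0.00	0.00	NS	0.00	1.01 × 10^−165
hsa-miR-27a-5p	MIMAT0004501	−1.12	−1.88	−1.89	NS	−1.55	−1.43	4.81 × 10^−2	3.57 × 10^−46	2.91 × 10^−56	NS	6.96 × 10^−46	1.75 × 10^−30
hsa-miR-222-3p	MIMAT0000279	1.09	−1.32	−2.14	−1.06	−1.54	−2.26	1.37 × 10^−3	2.89 × 10^−35	7.25 × 10^−256	4.89 × 10^−2	8.52 × 10^−96	0.00
hsa-miR-222-5p	MIMAT0004569	2.03	−4.15	−2.94	1.12	−2.08	−2.34	2.11 × 10^−65	8.41 × 10^−84	5.46 × 10^−84	1.39 × 10^−8	0.00	0.00
hsa-miR-212-3p	MIMAT0000269	NS	3.59	48.61	NS	1.70	1.56	NS	4.89 × 10^−3	3.21 × 10^−28	NS	1.28 × 10^−6	1.02 × 10^−4
hsa-miR-4284	MIMAT0016915	NS	6.08	11.55	NS	1.33	1.70	NS	8.03 × 10^−15	2.08 × 10^−29	NS	7.29 × 10^−3	2.05 × 10^−8
hsa-miR-33b-5p	MIMAT0003301	NS	1.71	7.66	NS	1.34	7.36	NS	1.90 × 10^−36	0.00	NS	6.39 × 10^−13	0.00
hsa-miR-7705	MIMAT0030020	NS	2.44	6.48	NS	1.70	3.30	NS	1.57 × 10^−7	1.12 × 10^−39	NS	1.98 × 10^−38	1.70 × 10^−203
hsa-miR-1301-3p	MIMAT0005797	NS	1.59	2.78	NS	1.85	1.64	NS	9.14 × 10^−21	2.66 × 10^−121	NS	5.24 × 10^−13	3.32 × 10^−8
hsa-miR-324-5p	MIMAT0000761	NS	1.50	2.40	NS	1.30	1.39	NS	7.82 × 10^−11	4.45 × 10^−57	NS	3.33 × 10^−7	2.21 × 10^−10
hsa-miR-192-5p	MIMAT0000222	NS	1.67	1.51	NS	2.44	1.43	NS	9.77 × 10^−229	2.97 × 10^−149	NS	0.00	7.08 × 10^−120
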