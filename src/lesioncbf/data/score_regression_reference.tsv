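subject	pipeline	r2	f	p	p_is_upper_bound	slope_sign
S01	blur4_native	0.84	43.34	0.0002	0	-
S01	blur4_mni	0.82	37.70	0.0003	0	-
S01	no_blur	0.78	28.67	0.0007	0	-
S02	blur4_native	0.86	48.30	0.0001	0	-
S02	blur4_mni	0.88	56.39	0.0001	1	-
S02	no_blur	0.90	73.98	0.0001	1	-
S03	blur4_native	0.45	6.52	0.03	0	-
S03	blur4_mni	0.46	8.82	0.03	0	-
S03	no_blur	0.29	3.34	0.10	0	-
S04	blur4_native	0.35	4.27	0.07	0	-
S04	blur4_mni	0.36	4.57	0.07	0	-
S04	no_blur	0.25	2.65	0.14	0	-
S05	blur4_native	0.50	7.99	0.02	0	-
S05	blur4_mni	0.48	7.27	0.03	0	-
S05	no_blur	0.46	6.73	0.03	0	-
S06	blur4_native	0.82	36.22	0.0003	0	-
S06	blur4_mni	0.81	33.69	0.0004	0	-
S06	no_blur	0.75	24.05	0.001	0	-
S07	blur4_native	0.23	2.40	0.16	0	-
S07	blur4_mni	0.18	1.75	0.22	0	-
S07	no_blur	0.17	1.67	0.23	0	-
S08	blur4_native	0.85	45.44	0.0001	0	-
S08	blur4_mni	0.81	34.52	0.0004	0	-
S08	no_blur	0.82	37.45	0.0003	0	-
S09	blur4_native	0.62	13.29	0.007	0	-
S09	blur4_mni	0.64	14.36	0.005	0	-
S09	no_blur	0.63	13.56	0.006	0	-
S10	blur4_native	0.71	19.63	0.002	0	+
S10	blur4_mni	0.66	15.70	0.004	0	+
S10	no_blur	0.57	10.44	0.01	0	+
S11	blur4_native	0.44	6.27	0.04	0	-
S11	blur4_mni	0.34	4.05	0.08	0	-
S11	no_blur	0.24	2.59	0.15	0	-
S12	blur4_native	0.94	127.32	0.0001	1	-
S12	blur4_mni	0.92	90.70	0.0001	1	-
S12	no_blur	0.86	50.82	0.0001	1	-
S13	blur4_native	0.02	0.16	0.70	0	none
S13	blur4_mni	0.01	0.07	0.80	0	none
S13	no_blur	0.01	0.07	0.80	0	none
S14	blur4_native	0.87	55.28	0.0001	1	-
S14	blur4_mni	0.90	75.63	0.0001	1	-
S14	no_blur	0.77	26.65	0.0009	0	-
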