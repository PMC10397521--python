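subject	age	sex	months_since_stroke	wab_aq	aphasia_type	lesion_volume_mm3	cavitation_volume_mm3	pct_cavitation
S01	51	M	24	59.0	Anomic	97078	35999	37.1
S02	59	M	38	65.9	Anomic	84630	20796	24.6
S03	50	M	85	75.3	Anomic	133145	52620	39.5
S04	71	F	24	67.1	Transcortical Motor	126144	13215	10.5
S05	61	M	121	74.5	Anomic	137945	53874	39.1
S06	24	F	23	55.3	Broca	133655	38924	29.1
S07	35	M	9	27.4	Broca	126164	6537	5.2
S08	47	M	44	75.6	Anomic	105421	42877	40.7
S09	43	F	49	80.6	Anomic	64703	21073	32.6
S10	81	F	60	74.1	Conduction	114099	31687	27.8
S11	73	M	55	79.6	Anomic	124145	64475	51.9
S12	45	M	14	78.6	Anomic	148123	14366	9.7
S13	50	M	70	59.4	Conduction	95516	28115	29.4
S14	60	M	9	52.4	Wernicke	132319	44429	33.6
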