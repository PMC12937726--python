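cohort	n_subjects	printed_per_100k	n_carriers	reproducible
European	349976	1444	5054	yes
African	36268	312	113	yes
Latinos	9570	170	16	no
Asian	12238	57	7	yes
South Asian	8960	1	0.1	yes
Total	434616	1267	5507	yes
TOPMED	264690	924	2447	yes
UK Biobank	54512	1626	951	no
Icelanders	35559	1534	545	no
FMBA	120762	2571	3105	yes
RUSEQ	12976	1318	171	yes
Genomed	37620	1881	708	no
RSMU	4657	1181	55	yes
RUSS-AGE	290	2411	7	no
Longevity	200	2500	5	yes
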