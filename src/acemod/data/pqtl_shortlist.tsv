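variant_id	gene	consequence	beta	p_value	maf_per_100k
rs8176743	ABO	missense	0.351	5.356 × 10^−105	6488
rs8176746	ABO	missense	0.35	8.358 × 10^−105	6496
rs8176747	ABO	missense	0.35	9.314 × 10^−105	6497
rs750712925	ACE	missense	−1.288	6.8 × 10^−15	82
rs3730025	ACE	missense	−1.217	3.306 × 10^−291	1534
rs757694144	ACE	missense	−1.349	1.50 × 10^−7	34
rs372416620	ACE	missense	0.371	6.70 × 10^−9	469
rs145825553	ADAMTS13	missense	0.394	2.40 × 10^−8	334
rs771742994	BCAS3	missense	−1.162	2.20 × 10^−12	88
rs117181531	DDX42	missense	0.429	4.50 × 10^−9	317
rs117595304	GBGT1	missense	−0.363	1.20 × 10^−9	457
rs367887663	MFSD6L	missense	0.505	3.50 × 10^−8	166
rs1352161075	MILR1	missense	0.376	1.20 × 10^−10	539
rs201723860	SMARCD2	missense	0.478	7.00 × 10^−8	242
rs750512077	STRADA	missense	−0.405	2.80 × 10^−9	352
rs370863314	TANC2	missense	0.479	8.20 × 10^−9	232
rs780968826	TEX2	missense	0.366	9.00 × 10^−10	486
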