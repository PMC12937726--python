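variant_id	gene	cdna	1737	1340	181	614	615	HSY004	HWY602	JQW970	KJB939	OTS421	OTX780	SRZ900	TXM676	VYA317	XLK932	gnomad_per_100k	fmba_per_100k
rs148688256	CD34	c.398C>T	-	-	-	-	-	Het	-	Het	-	-	-	-	-	-	Het	192	1020
rs146206869	TMEM240	c.454G>A	-	-	-	Het	-	-	-	-	-	-	Het	-	Het	-	-	3364	2825
rs34639461	CHST15	c.98C>T	-	Het	-	-	-	-	-	-	-	-	Het	-	Het	-	-	2984	2880
rs11037840	ACCSL	c.133G>A	-	-	-	-	-	-	Het	Het	-	-	-	Het	-	-	-	450	1220
rs61754226	MYRFL	c.2072C>T	Het	-	-	-	-	-	-	-	-	-	Het	-	-	-	Het	690	620
rs149007412	TMCC3	c.564G>A	-	Het	-	-	-	-	-	Het	-	-	-	-	-	Het	-	674	1270
rs139932140	LTBP2	c.4769T>C	-	-	-	-	-	-	-	Het	-	-	-	Het	Het	-	-	773	1805
rs112536229	RPAP1	c.146C>T	Het	-	Het	-	-	-	-	Het	-	-	-	-	-	-	-	1157	1680
rs2279997	CFAP161	c.850C>T	-	-	-	-	Het	-	Het	Het	-	-	-	-	-	-	-	1080	1290
rs45478794	PKD1	c.10529C>T	Het	-	-	-	-	-	-	Het	Het	Het	-	-	-	Het	-	1320	1820
rs35923277	ARMC5	c.508A>G	-	-	-	-	-	-	-	-	Het	-	Het	Het	-	-	-	4147	4510
rs184583062	ZNF469	c.1994C>T	-	-	-	-	-	-	-	Het	Het	-	Het	-	-	-	-	783	900
rs138935423	KIF1C	c.2105C>T	-	Het	-	Het	Het	-	-	-	-	Het	-	-	-	-	-	752	1280
rs112980285	PER1	c.2575C>T	-	-	-	-	-	-	-	Het	-	-	-	Het	-	Het	-	2368	1810
rs79261438	PIEZO2	c.4203C>G	Het	-	Het	-	-	-	-	-	-	-	Het	-	-	Het	-	2986	2700
rs36088948	HSH2D	c.410C>T	-	-	Het	-	-	-	-	-	Het	-	-	-	Het	Het	-	6876	4430
rs75734024	SCAMP4	c.596C>T	-	Het	-	-	-	-	-	-	Het	-	-	-	-	Het	-	1726	1460
rs1667364	ZNF568	c.1088C>T	-	-	-	-	-	-	-	-	Het	-	Het	-	-	Het	-	1874	1340
rs3030812	CEACAM21	c.253_255dup	-	-	-	-	Het	-	-	-	-	Het	-	-	Het	-	-	4181	3740
rs78133615	CEACAM21	c.333C>G	-	-	-	-	Het	-	-	-	-	Het	-	-	Het	-	-	4109	3730
rs11085080	PLIN5	c.73C>T	-	-	-	-	-	-	Hom	-	Het	Het	-	-	-	-	-	6443	4910
rs78530808	NOP53	c.91G>C	-	-	-	-	Het	-	Het	-	-	-	-	Het	-	-	-	1801	2850
rs200483574	NRP2	c.2716_2717insA	-	-	Het	-	Het	-	-	-	-	Het	-	-	-	-	-	4437	4340
rs11423284	GCFC2	c.1812+399dup	-	-	Het	Het	-	-	-	-	-	-	Het	-	-	-	-	3960	1638
rs137853909	MKKS	c.1015A>G	Het	-	-	-	-	Het	-	-	-	-	Het	-	-	-	-	417	1030
rs6142471	CNBD2	c.622A>G	-	-	-	-	Het	-	-	Het	-	Het	-	-	-	-	-	112	749
rs5743523	BPI	c.1051C>T	-	-	-	Het	Het	-	Het	-	-	-	Het	-	-	-	-	2502	4070
rs61729471	SHANK3	c.2347G>A	-	-	-	-	-	Het	-	-	-	-	-	Het	-	Het	-	3357	4580
rs77852202	HCLS1	c.1162G>A	Het	-	-	-	-	Het	-	-	-	Het	-	-	-	-	-	5512	3560
rs78190191	DLG1	c.2357G>A	Het	-	Het	-	-	-	-	-	-	Het	-	-	-	-	-	2017	3080
rs74764772	CCDC149	c.1525C>T	-	Het	-	-	-	-	-	Het	-	-	-	-	Het	-	-	946	2600
rs144600070	DNAJC21	c.1024G>A	-	-	-	-	-	Het	-	-	Het	-	-	-	-	-	Het	457	859
rs41285023	PHACTR2	c.4G>A	Het	-	-	-	-	-	-	-	-	Het	Het	-	-	-	-	2244	1270
rs56300302	TBC1D32	c.3695A>C	Het	-	-	Het	-	-	-	Het	-	-	-	-	-	-	-	1632	1638
rs3800381	SCUBE3	c.1229C>T	-	-	-	-	-	-	-	Het	-	-	-	-	Het	-	Het	198	392
rs34666277	TSC22D4	c.1150C>T	Het	-	-	-	Hom	-	-	-	-	-	-	-	-	Het	-	626	800
rs138450169	CUX1	c.1573C>G	-	Het	-	Het	-	-	-	-	Het	-	-	-	-	-	-	689	1244
rs138381817	CRB2	c.278G>A	Het	-	-	-	-	-	Het	-	-	-	-	Het	-	-	-	730	896
rs189947178	DENND1A	c.2534C>A	Het	Het	-	-	-	-	-	-	-	-	-	Het	-	-	-	679	896
rs11143384	TMC1	c.421C>T	-	Het	Het	Hom	-	-	-	-	-	-	-	-	-	-	-	957	990
rs117994893	MAN1B1	c.1896+22G>A	Het	-	Het	-	-	-	-	Het	-	-	-	-	-	-	-	3454	4550
rs5969783	TXLNG	c.736A>G	-	-	Het	-	Het	-	-	-	-	-	-	-	-	-	Het	2885	2600
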