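# qsmine packaged reference: the 77 KEGG Orthology entries of the "quorum sensing"
# pathway (ko02024) observed across the acidophile cohort. Columns:
# ko_id	protein_name	cog_ids (comma-separated, may be empty)	definition
K01580	GadA/B	COG0076	Glutamate decarboxylase (EC 4.1.1.15)
K01657	TrpE	COG0147	Anthranilate synthase component I [EC:4.1.3.27]
K01658	TrpG	COG0512	Anthranilate synthase component II (EC 4.1.3.27)
K01897	RpfB	COG0318,COG1022	Long-chain acyl-CoA synthetase (EC 6.2.1.3)
K02031	DdpD	COG0444,COG1123	Peptide/nickel transport system ATP-binding protein
K02033	ABC.PE.P	COG0601	Peptide/nickel transport system permease protein
K02034	ABC.PE.P1	COG1173	Peptide/nickel transport system permease protein
K02035	ABC.PE.S	COG0747	Peptide/nickel transport system substrate-binding protein
K03070	SecA	COG0653	Preprotein translocase subunit SecA (EC 7.4.2.8)
K03071	SecB	COG1952	Preprotein translocase subunit SecB
K03073	SecE	COG0690	Preprotein translocase subunit SecE
K03075	SecG	COG1314	Preprotein translocase subunit SecG
K03076	SecY	COG0201	Preprotein translocase subunit SecY
K03106	SRP54	COG0541	Signal recognition particle subunit SRP54 (EC 3.6.5.4)
K03110	FtsY	COG0552	Fused signal recognition particle receptor
K03210	YajC	COG1862	Preprotein translocase subunit YajC
K03217	YidC	COG0706	YidC/Oxa1 family membrane protein insertase
K10823	OppF	COG4608	Oligopeptide transport system ATP-binding protein
K10914	Clp	COG0664	CRP/FNR family transcriptional regulator, cyclic AMP receptor protein
K11752	RibD	COG0117,COG1985	Diaminohydroxy phosphoribosyl aminopyrimidine deaminase/5-amino-6-(5-phosphoribosylamino) uracil reductase (EC 3.5.4.26 1.1.1.193)
K01114	Plc	COG1923	Phospholipase C (EC 3.1.4.3)
K03666	Hfq	COG3512	Host factor-I protein
K07667	KdpE	COG0745	Two-component system, OmpR family, KDP operon response regulator KdpE
K13075	AhlD	COG0491	N-acyl homoserine lactone hydrolase (EC 3.1.1.81)
K20527	TrbB	COG4962	Type IV secretion system protein TrbB (EC 7.4.2.8)
K20528	TrbC	COG3838	Type IV secretion system protein TrbC
K20529	TrbD	COG5268	Type IV secretion system protein TrbD
K20530	TrbE	COG4962	Type IV secretion system protein TrbE (EC 7.4.2.8)
K20531	TrbF	COG3701	Type IV secretion system protein TrbF
K20532	TrbG	COG3504	Type IV secretion system protein TrbG
K20533	TrbI	COG2948	Type IV secretion system protein TrbI
K07344	TrbL	COG3846	Type IV secretion system protein TrbL
K01497	RibA	COG0807	GTP cyclohydrolase II (EC 3.5.4.25)
K01995	LivG	COG0411	Branched-chain amino acid transport system ATP-binding protein
K01996	LivF	COG0410	Branched-chain amino acid transport system ATP-binding protein
K01997	LivH	COG0559	Branched-chain amino acid transport system permease protein
K01998	LivM	COG4177	Branched-chain amino acid transport system permease protein
K01999	LivK	COG0683	Branched-chain amino acid transport system substrate-binding protein
K02032	DdpF	COG1123,COG1124	Peptide/nickel transport system ATP-binding protein
K02052	ABC.SP.A	COG3842	Putative spermidine/putrescine transport system ATP-binding protein
K02053	ABC.SP.P	COG1177	Putative spermidine/putrescine transport system permease protein
K02054	ABC.SP.P2	COG1176	Putative spermidine/putrescine transport system permease protein
K02055	ABC.SP.S	COG0687	Putative spermidine/putrescine transport system substrate-binding protein
K06998	PhzF	COG0384	Trans-2,3-dihydro-3-hydroxyanthranilate isomerase (EC 5.3.3.17)
K07699	Spo0A	COG0784	Two-component system, response regulator, stage 0 sporulation protein A
K20327	XagB	COG1215	Glycosyltransferase XagB
K09936	ToxF	COG3238	Bacterial/archaeal transporter family-2 protein
K15580	OppA	COG4166	Oligopeptide transport system substrate-binding protein
K18139	ToxI	COG1538	Outer membrane protein, multidrug efflux system
K20265	GadC	COG0531	Glutamate:GABA antiporter
K20266	TrbJ	COG5314	Type IV secretion system protein TrbJ
K07666	QseB	COG0745	Two-component system, OmpR family, response regulator
K10715	RpfC	COG0642,COG0784	Two-component system, sensor histidine kinase RpfC (EC 2.7.13.3)
K13815	RpfG	COG3437	Two-component system, response regulator RpfG
K13816	RpfF	COG1024	DSF synthase
K01626	PhzC	COG0722	3-Deoxy-7-phosphoheptulonate synthase (EC 2.5.1.54)
K09823	Zur	COG0735	Fur family transcriptional regulator, zinc uptake regulator
K10555	LsrB	COG1879	AI-2 transport system substrate-binding protein
K20249	RaiI	COG3916	Acyl homoserine lactone synthase
K20326	XagA		Protein XagA
K02490	Spo0F	COG0784	Two-component system, response regulator, stage 0 sporulation protein F (EC 2.3.1.184)
K07692	DegU	COG2197	Two-component system, NarL family, response regulator DegU
K14982	CiaH	COG0642	Two-component system, OmpR family, sensor histidine kinase CiaH (EC 2.7.13.3)
K15583	OppD	COG0444	Oligopeptide transport system ATP-binding protein
K20332	ToxC	COG2319	Toxoflavin biosynthesis protein ToxC
K20333	ToxD	COG1262	Toxoflavin biosynthesis protein ToxD
K15581	OppB	COG0601	Oligopeptide transport system permease protein
K15582	OppC	COG1173	Oligopeptide transport system permease protein
K20334	CviR	COG2771,COG2197	LuxR family transcriptional regulator, quorum-sensing system regulator CviR
K02402	FlhC		Flagellar transcriptional activator FlhC
K07711	QseE	COG0642	Two-component system, NtrC family, sensor histidine kinase GlrK (EC 2.7.13.3)
K07715	QseF	COG2204	Two-component system, NtrC family, response regulator GlrR
K13061	RhlI	COG3916	Acyl homoserine lactone synthase (EC 2.3.1.184)
K18100	RhlA	COG0596	Rhamnosyltransferase subunit A (EC 2.4.1.-)
K18101	RhlB	COG1819	Rhamnosyltransferase subunit B (EC 2.4.1.-)
K12990	RhlC	COG1216	Rhamnosyltransferase (EC 2.4.1.-)
K18306	ToxG	COG0845	Membrane fusion protein, multidrug efflux system
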