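genome_id	organism	replicon_id	size_bp	replicon_class	gc	copy_number	replication_module	partitioning	mobility	accession
DSM14862	Sulfitobacter indolifex DSM 14862	cDSM14862	3271523	chromosome	60.0	1.0	DnaA	yes	no	CP084951
DSM14862	Sulfitobacter indolifex DSM 14862	pDSM14862_a	313826	plasmid	55.4	0.5	RepABC-20	yes	no	CP084952
DSM14862	Sulfitobacter indolifex DSM 14862	pDSM14862_b	307297	plasmid	56.1	0.8	DnaA-like-I	yes	no	CP084953
DSM14862	Sulfitobacter indolifex DSM 14862	pDSM14862_c	200719	chromid	60.3	0.8	RepABC-8	yes	no	CP084954
DSM14862	Sulfitobacter indolifex DSM 14862	pDSM14862_d	160516	plasmid	56.5	0.8	DnaA-like-II	yes	no	CP084955
DSM14862	Sulfitobacter indolifex DSM 14862	pDSM14862_e	123234	plasmid	57.1	0.6	RepABC-4	yes	T4SS	CP084956
DSM14862	Sulfitobacter indolifex DSM 14862	pDSM14862_f	104164	plasmid	59.8	0.7	RepABC-7	yes	T4SS	CP084957
DSM14862	Sulfitobacter indolifex DSM 14862	pDSM14862_g	17291	plasmid	54.9	5.3	RepQ	no	MOBP	CP084958
DSM110277	Sulfitobacter pontiacus DSM 110277	cDSM110277	3012962	chromosome	60.5	1.0	DnaA	yes	no	CP084959
DSM110277	Sulfitobacter pontiacus DSM 110277	pDSM110277_a	239416	plasmid	60.2	0.7	RepABC-10	yes	T4SS	CP084960
DSM110277	Sulfitobacter pontiacus DSM 110277	pDSM110277_b	230345	chromid	59.7	0.7	DnaA-like-II	yes	no	CP084961
DSM110277	Sulfitobacter pontiacus DSM 110277	pDSM110277_c	177750	chromid	60.3	0.6	DnaA-like-I	yes	no	CP084962
DSM110277	Sulfitobacter pontiacus DSM 110277	pDSM110277_d	128813	plasmid	59.6	0.5	RepABC-9-1	yes	T4SS	CP084963
DSM110277	Sulfitobacter pontiacus DSM 110277	pDSM110277_e	53945	plasmid	57.0	1.8	RepABC-8	yes	no	CP084964
DSM110277	Sulfitobacter pontiacus DSM 110277	pDSM110277_f	6732	plasmid	52.1	124.3	RepY	no	MOBQ	CP084965
DSM110093	Sulfitobacter sp. DSM 110093	cDSM110093	3434207	chromosome	59.7	1.0	DnaA	yes	MOBV	CP085167
DSM110093	Sulfitobacter sp. DSM 110093	pDSM110093_a	336544	plasmid	55.3	1.1	RepABC-21	yes	no	CP085168
DSM110093	Sulfitobacter sp. DSM 110093	pDSM110093_b	273772	plasmid	54.9	1.1	RepABC-20	yes	no	CP085169
DSM110093	Sulfitobacter sp. DSM 110093	pDSM110093_c	268356	chromid	59.7	1.0	RepABC-8	yes	no	CP085170
DSM110093	Sulfitobacter sp. DSM 110093	pDSM110093_d	21520	plasmid	52.6	4.3	RepA	no	MOBP	CP085171
DSM110093	Sulfitobacter sp. DSM 110093	pDSM110093_e	5635	plasmid	53.9	23.4	RepW	no	no	CP085172
DSM109990	Sulfitobacter dubius DSM 109990	cDSM109990	3274709	chromosome	60.2	1.0	DnaA	yes	no	CP085144
DSM109990	Sulfitobacter dubius DSM 109990	pDSM109990_a	284454	plasmid	55.4	1.2	RepB-I	yes	MOBP	CP085145
DSM109990	Sulfitobacter dubius DSM 109990	pDSM109990_b	247035	chromid	60.5	0.9	RepABC-8	yes	no	CP085146
DSM109990	Sulfitobacter dubius DSM 109990	pDSM109990_c	183486	plasmid	57.6	0.9	RepABC-2	yes	no	CP085147
DSM109990	Sulfitobacter dubius DSM 109990	pDSM109990_d	108277	plasmid	59.9	0.6	RepABC-1	yes	T4SS	CP085148
DSM109990	Sulfitobacter dubius DSM 109990	pDSM109990_e	47721	plasmid	58.7	2.6	RepA_a	no	MOBQ	CP085149
DSM109990	Sulfitobacter dubius DSM 109990	pDSM109990_f	6286	plasmid	59.7	9.5	RepA_b	no	MOBQ	CP085150
DSM109990	Sulfitobacter dubius DSM 109990	pDSM109990_g	4878	plasmid	52.3	12.5	RepA_c	no	no	CP085151
DSM109990	Sulfitobacter dubius DSM 109990	pDSM109990_h	4609	plasmid	58.4	12.4	RepA_d	no	MOBV	CP085152
DSM109990	Sulfitobacter dubius DSM 109990	pDSM109990_i	3857	plasmid	55.0	15.3	RepW	no	no	CP085153
DSM107133	Pseudosulfitobacter sp. DSM 107133	cDSM107133	3635847	chromosome	61.1	1.0	DnaA	yes	no	CP085154
DSM107133	Pseudosulfitobacter sp. DSM 107133	pDSM107133_a	571401	chromid	61.0	1.1	RepABC-3	yes	no	CP085155
DSM107133	Pseudosulfitobacter sp. DSM 107133	pDSM107133_b	246683	chromid	61.1	0.6	RepB-I	yes	no	CP085156
DSM107133	Pseudosulfitobacter sp. DSM 107133	pDSM107133_c	158961	plasmid	60.3	0.5	RepABC-11	yes	T4SS	CP085157
DSM107133	Pseudosulfitobacter sp. DSM 107133	pDSM107133_d	135500	plasmid	58.0	0.4	RepABC-9-1	yes	MOBP	CP085158
DSM107133	Pseudosulfitobacter sp. DSM 107133	pDSM107133_e	129047	plasmid	58.4	0.4	RepABC-5	yes	T4SS	CP085159
DSM107133	Pseudosulfitobacter sp. DSM 107133	pDSM107133_f	128511	plasmid	60.2	0.4	RepABC-1	yes	T4SS	CP085160
DSM107133	Pseudosulfitobacter sp. DSM 107133	pDSM107133_g	105694	plasmid	60.4	0.4	RepABC-9-2	yes	T4SS	CP085161
DSM107133	Pseudosulfitobacter sp. DSM 107133	pDSM107133_h	65426	chromid	63.6	0.6	RepB-III	yes	no	CP085162
DSM107133	Pseudosulfitobacter sp. DSM 107133	pDSM107133_i	17449	plasmid	53.1	3.8	RepA_a	no	no	CP085163
DSM107133	Pseudosulfitobacter sp. DSM 107133	pDSM107133_j	7190	plasmid	59.6	9.1	RepA_b	no	MOBQ	CP085164
DSM107133	Pseudosulfitobacter sp. DSM 107133	pDSM107133_k	5670	plasmid	59.0	8.6	RepL	no	MOBQ	CP085165
DSM107133	Pseudosulfitobacter sp. DSM 107133	pDSM107133_l	4511	plasmid	53.5	21.3	RepW	no	MOBV	CP085166
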