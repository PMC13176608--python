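# The 37 curated C-terminal-domain motifs of the ten reference TFRs: consensus string
# (ambiguity letters B={D,N}, Z={E,Q}, J={I,L}), the sequence matched in the named
# protein, 1-based inclusive positions in full-protein numbering, the published FDR
# q-value of that hit, and the number of superfamily sequences the motif was found in.
# Row tFadR-2 is transcribed as printed: a 15-residue matched sequence against a
# 14-position span (110-123); flagged via the discrepancy column, not corrected.
protein	subfamily	motif_id	consensus	matched	start	stop	q_value	n_sequences	discrepancy
Bsu_FadR	EI	FadR-1	EDILISLFZE	EDILISLFKE	51	60	5.29e-08	936
Bsu_FadR	EI	FadR-2	LAIVTQLELRQSNKE	LAIVTQLELRQSNLE	100	114	3.75e-13	1269
Bsu_FadR	EI	FadR-3	INEVLKGYL	INEILKGYL	119	127	1.43e-07	278
Bsu_FadR	EI	FadR-4	MIFGAJDET	MIFGTIDET	155	163	2.37e-07	679
Eco_TetR	K	TetR-1	DREALLAALAAZGFE	NKRALLDALAVEILA	47	61	2.40e-05	11305
Eco_TetR	K	TetR-2	NHTHSVPRAG	HHDYSLPAAG	63	72	4.07e-06	192
Eco_TetR	K	TetR-3	ALLAHRDGARVVAGT	ALLRYRDGAKVHLGT	89	103	2.51e-11	3098
Eli_EilR	C	EilR-1	RLHAMLGSEDG	QLFSALGSEDG	82	92	3.98e-07	282
Eli_EilR	C	EilR-2	DGGFEPYIKLWREAQ	DGRLEPYIRLWRQAQ	91	105	5.80e-14	288
Eli_EilR	C	EilR-3	PHIKDAYLLTMZMWH	PEIKSAYLLTMNLWH	112	126	5.44e-13	372
Eli_EilR	C	EilR-4	AWRLIALVCGLDGIY	AWRLISLVCGLDGIY	152	166	1.06e-14	412
Mtu_EthR	G	EthR-1	WRNGIEAFFETFGSH	WRTGINVFFETFGSH	103	117	2.87e-15	442
Mtu_EthR	G	EthR-2	WSGFMQKWIDHTAAV	WSTFMQKWIAYTAAV	138	152	5.01e-15	392
Mtu_EthR	G	EthR-3	PARDLATALNWMNER	PAHELATALNLMNER	167	181	3.80e-13	888
Mtu_EthR	G	EthR-4	AIDTLAHIWLRSJYG	VLDTLVHIWVTSIYG	199	213	1.88e-11	1270
Mtu_KstR2	EB	KstR2-1	STFLDELWAGYDAVL	RGFLDWLFARYRDIV	63	77	6.27e-07	1121
Mtu_KstR2	EB	KstR2-2	AVAIYQREMHHL	QVVIYQDEAQRL	104	115	3.42e-06	2301
Mtu_KstR2	EB	KstR2-3	EERNRZQRK	EDRNKQQRK	125	133	5.28e-07	165
Mtu_KstR2	EB	KstR2-4	DLDVRLTY	DLDVDLVY	151	158	6.56e-06	191
Mtu_KstR2	EB	KstR2-5	YRFIRDTVW	YRFIRDTTW	158	166	1.36e-08	1505
Pae_DesT	N	DesT-1	ITSDLAADLARMPKL	ITDDLAADLALLNKM	132	146	9.69e-10	898
Pae_DesT	N	DesT-2	VRQLRMIAKGAYHWR	THQLRFIMIGGKHWH	191	205	3.82e-07	2658
Pae_DesT	N	DesT-3	LKHWQGLG	GKHWHGLP	201	208	4.94e-05	296
Ppu_TtgR	EA	TtgR-1	EPDPLGCMRKLLIHL	EVDPLGCMRKLLLQV	82	96	8.68e-12	769
Ppu_TtgR	EA	TtgR-2	RRVFEILFHKCEFTD	RRINEILHHKCEFTD	107	121	7.04e-14	3002
Ppu_TtgR	EA	TtgR-3	CDLRQQRQT	CEIRQQRQS	124	132	1.61e-06	466
Sen_RamR	N	RamR-1	KDELJNALYLHLKAD	KDELINTLYLHLKQD	51	65	5.96e-14	1422
Sen_RamR	N	RamR-2	PKENARNIWNSYIDW	AKMMTRFIWNSYISW	81	95	5.74e-06	200
Sen_RamR	N	RamR-3	HRAJRQLAV	HRAIRQLAV	103	111	1.85e-08	151
Sen_RamR	N	RamR-4	MFPELRELCHRS	MFPELRDLCHRS	126	137	1.02e-12	303
Sen_RamR	N	RamR-5	SDEARAFGD	SDEYRAFGD	144	152	2.51e-08	169
Sen_RamR	N	RamR-6	QAERYRKSGFEAFWH	RAGEYIALGFEAMWR	172	186	8.28e-05	271
Sli_EbrA	C	EbrA-1	TKDELLAAALEHVAE	TLDDLMVAALRQANE	51	65	1.06e-08	9607
Sli_EbrA	C	EbrA-2	GFAKVVAARGALEDP	GFARVVAAHPALSDP	66	80	9.63e-12	287
Sli_EbrA	C	EbrA-3	DRTGVELEY	DRTGVELEY	99	107	6.61e-08	301
Tth_FadR	L	tFadR-1	PYKEAVLLDYG	PYKEAVLLDYG	52	62	2.54e-10	85
Tth_FadR	L	tFadR-2	YELLNPDPVRAKAAF	YELLNPDPVRARAAF	110	123	5.01e-15	85	span_shorter_than_matched
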