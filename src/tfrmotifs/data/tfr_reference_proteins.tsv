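# Ten well-characterized TetR-family regulators whose CTD motifs ship with this package.
# Table 1 of the source study; protein tag Eli_EilR normalized (printed once as Eli_EliR).
protein	subfamily	uniprot_id	organism	full_name	role
Bsu_FadR	EI	P94548	Bacillus subtilis	Fatty acyl-CoA dependent transcription factor	Fatty acid metabolism
Eco_TetR	K	P0ACT4	Escherichia coli	Tetracycline repressor	Antibiotic resistance
Eli_EilR	C	E3G817	Enterobacter lignolyticus	Multidrug-binding repressor	Multidrug resistance
Mtu_EthR	G	P9WMC1	Mycobacterium tuberculosis	Transcriptional regulator EthR	Antibiotic resistance
Mtu_KstR2	EB	P9WMB9	Mycobacterium tuberculosis	Transcriptional repressor KstR2	Cholesterol degradation
Pae_DesT	N	Q9HUS3	Pseudomonas aeruginosa	Transcriptional repressor DesT	Fatty acid metabolism
Ppu_TtgR	EA	Q9AIU0	Pseudomonas putida	Transcriptional regulator TtgR	Regulation of efflux pump
Sen_RamR	N	Q8ZR43	Salmonella enterica	Multidrug-resistance regulator RamR	Multidrug resistance
Sli_EbrA	C	Q79SH7	Streptomyces lividans	Transcriptional repressor EbrA	Multidrug resistance
Tth_FadR	L	Q5SM42	Thermus thermophilus	Fatty acyl-CoA dependent transcription factor	Fatty acid metabolism
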