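# PROSITE patterns proposed for the most specific motif of each reference TFR,
# with the published expected-random-match count in 50,000,000 residues and the
# published YES/NO verdict on suitability as a signature. FadR-3's ERM is printed
# "n/a" (close to zero). Patterns transcribed as printed, including unhyphenated
# letter runs in the FadR-3 row.
motif_id	pattern	erm	signature
DesT-3	[LAG]-[KR]-H-W-[QRH]-G-L-[GSP]	4.77e-02	NO
EbrA-3	[DE]-R-x(2)-V-E-L-E-Y	0.21	NO
EilR-2	[DE]-x(3)-[ED]-P-[YH]-[IV]-x-L-W-R-[EQ]-[AG]-[QL]	2.51e-05	YES
EthR-1	[WI]-R-x(2)-I-x(2)-F-x(3)-[FS]-x(2)-H	0.94	NO
FadR-3	IN-x-[VI]-LK-[GPE]-YL	n/a	YES
KstR2-3	[ED]-[DE]-[RM]-N-[RK]-[QE]-Q-R-K	2.97e-03	YES
RamR-2	K-x(3)-[RH]-x-[IV]-W-N-S-Y-[IV]-x-W	4.77e-05	YES
TetR-2	[NHR]-H-[TD]-[HAY]-[SF]-x-P-x-x-[DG]	1.1	NO
TetR-3	A-L-L-x-[YH]-R-D-[GD]-A-x(2)-H-x-G-T	3.82e-06	YES
tFadR-2	Y-E-x(2)-N-P-[DN]-P-x-R-A-x(2)-A	2.97e-04	YES
TtgR-3	C-[DE]-x-R-[RQ]-Q-R-[QR]	8.28e-02	YES
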