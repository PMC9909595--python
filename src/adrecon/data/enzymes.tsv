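name	recognition	cut_top	cut_bottom
NotI	GCGGCCGC	2	6
SrfI	GCCCGGGC	4	4
PmeI	GTTTAAAC	4	4
SwaI	ATTTAAAT	4	4
SapI	GCTCTTC	8	11
SbfI	CCTGCAGG	6	2
EcoRI	GAATTC	1	5
EcoRV	GATATC	3	3
ClaI	ATCGAT	2	4
NheI	GCTAGC	1	5
XbaI	TCTAGA	1	5
SpeI	ACTAGT	1	5
FseI	GGCCGGCC	6	2
XmaI	CCCGGG	1	5
SmaI	CCCGGG	3	3
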