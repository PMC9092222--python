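strain	n_tirs	active_domain_id	product
Bacteroides coprophilus DSM 18228	4	none	N/A
Bacteroides dorei DSM 17855	1	none	N/A
Bacteroides ovatus ATCC 8483	3	Bovatus_RS22005.TIR_2.1	cADPR
Bacteroides thetaiotaomicron 3731	3	AMN69_RS06490.TIR_2.1	cADPR
Bacteroides thetaiotaomicron 3731		AMN69_RS28245.TIR_2.1	cADPR
Bacteroides thetaiotaomicron 7330	2	Btheta7330_RS03065.TIR_2.1	v-cADPR-x
Bacteroides thetaiotaomicron 7330		Btheta7330_RS23835.TIR_2.1	cADPR
Bacteroides uniformis BUAKA3JSW	3	none	N/A
Bacteroides vulgatus ATCC 8482	1	none	N/A
Bacteroides xylanisolvens XB1A	3	BXY_39700.TIR_2.1	v-cADPR-x
Bifidobacterium longum BLJG463	1	none	N/A
Blautia hansenii DSM 20583	2	none	N/A
Clostridium bolteae ATCC BAA 613	2	CLOBOL_01188.TIR_2.1	ADPR
Clostridium hathewayi DSM 13479	0	none	N/A
Clostridium scindens ATCC 35704	1	none	N/A
Clostridium symbiosum CSTS8243C	1	none	N/A
Collinsella aerofaciens ATCC 25986	1	none	N/A
Coprococcus eutactus ATCC 27759	4	COPEUT_02740.TIR_2.1	ADPR
Dorea formicigenerans ATCC 27755	1	DORFOR_RS09155.TIR_2.1	v-cADPR-y
Dorea formicigenerans DFSSTS7063	1	none	N/A
Enterococcus avium EASS39	1	none	N/A
Eubacterium cylindroides DSM 3983	1	HMPREF0367_01592.TIR_2.1	ADPR
Proteus penneri ATCC 35198	1	PROPEN_03896.TIR_2.1	ADPR
Roseburia intestinalis L1 82	2	ROSINTL182_07906.TIR_2.1	v-cADPR-x
Ruminococcus torques RTSSTS7063	1	none	N/A
Streptococcus constellatus SCSS39	2	none	N/A
Streptococcus pasteurianus SPSS39	2	none	N/A
Subdoligranulum variabile DSM 15176	0	none	N/A
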