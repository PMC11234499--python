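BUFFA_HYPOXIA	Buffa-style common hypoxia metagene (52 genes; editable)	ACOT7	ADM	AK4	ALDOA	ANKRD37	ANLN	BNIP3	CA9	CDKN3	CHCHD2	CORO1C	CTSV	DCBLD1	DDIT4	ENO1	ESRP1	FAM83B	GAPDH	GPI	HILPDA	HK2	KIF20A	KIF4A	LDHA	LRRC42	MAD2L2	MAP7D1	MCTS1	MIF	MRGBP	MRPL13	MRPS17	NDRG1	P4HA1	PFKP	PGAM1	PGK1	PNP	PSMA7	PSRC1	SEC61G	SHCBP1	SLC16A1	SLC25A32	SLC2A1	TPI1	TUBA1B	TUBA1C	TUBB6	UTP11	VEGFA	YKT6
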