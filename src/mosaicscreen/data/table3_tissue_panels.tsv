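parent	gene	variant	tissue	method	value	tag
M1	USP7	c.238A>T	blood	es	3
M1	USP7	c.238A>T	blood	amplicon_ngs	9
M1	USP7	c.238A>T	blood	ddpcr	2.13
M1	USP7	c.238A>T	buccal	amplicon_ngs	1
M1	USP7	c.238A>T	buccal	ddpcr	0.3
M1	USP7	c.238A>T	saliva	amplicon_ngs	8
M1	USP7	c.238A>T	saliva	ddpcr	4.78
M1	USP7	c.238A>T	urine	amplicon_ngs	2
M1	USP7	c.238A>T	urine	ddpcr	0.86
M1	USP7	c.238A>T	hair	amplicon_ngs	0.03
M1	USP7	c.238A>T	nail	amplicon_ngs	5
M2	PTPN11	c.923A>G	blood	es	1
M2	PTPN11	c.923A>G	blood	amplicon_ngs	0.3
M2	PTPN11	c.923A>G	blood	ddpcr	ND
M2	PTPN11	c.923A>G	buccal	amplicon_ngs	0.21
M2	PTPN11	c.923A>G	buccal	ddpcr	ND
M2	PTPN11	c.923A>G	saliva	amplicon_ngs	0.1
M2	PTPN11	c.923A>G	saliva	ddpcr	NT
M2	PTPN11	c.923A>G	urine	amplicon_ngs	0.22
M2	PTPN11	c.923A>G	urine	ddpcr	NT
M2	PTPN11	c.923A>G	hair	amplicon_ngs	0.15
M2	PTPN11	c.923A>G	nail	amplicon_ngs	NA
M3	PTPN11	c.923A>G	blood	es	1
M3	PTPN11	c.923A>G	blood	amplicon_ngs	0.3
M3	PTPN11	c.923A>G	blood	ddpcr	DEG
M3	PTPN11	c.923A>G	buccal	amplicon_ngs	0.2
M3	PTPN11	c.923A>G	buccal	ddpcr	ND
M3	PTPN11	c.923A>G	saliva	amplicon_ngs	0.2
M3	PTPN11	c.923A>G	saliva	ddpcr	NT
M3	PTPN11	c.923A>G	urine	amplicon_ngs	0.2
M3	PTPN11	c.923A>G	urine	ddpcr	NT
M3	PTPN11	c.923A>G	hair	amplicon_ngs	NA
M3	PTPN11	c.923A>G	nail	amplicon_ngs	NA
M4	COL11A1	c.3816+2dupT	blood	es	2.8
M4	COL11A1	c.3816+2dupT	blood	amplicon_ngs	0.2	HC
M4	COL11A1	c.3816+2dupT	blood	ddpcr	ND
M4	COL11A1	c.3816+2dupT	buccal	amplicon_ngs	ND
M4	COL11A1	c.3816+2dupT	buccal	ddpcr	ND
M4	COL11A1	c.3816+2dupT	saliva	amplicon_ngs	ND
M4	COL11A1	c.3816+2dupT	saliva	ddpcr	DEG
M4	COL11A1	c.3816+2dupT	urine	amplicon_ngs	ND
M4	COL11A1	c.3816+2dupT	urine	ddpcr	ND
M4	COL11A1	c.3816+2dupT	hair	amplicon_ngs	ND
M4	COL11A1	c.3816+2dupT	nail	amplicon_ngs	ND
M5	CACNA1C	c.694G>C	blood	es	1
M5	CACNA1C	c.694G>C	blood	amplicon_ngs	2
M5	CACNA1C	c.694G>C	blood	ddpcr	ND
M5	CACNA1C	c.694G>C	buccal	amplicon_ngs	ND
M5	CACNA1C	c.694G>C	buccal	ddpcr	ND
M5	CACNA1C	c.694G>C	saliva	amplicon_ngs	ND
M5	CACNA1C	c.694G>C	saliva	ddpcr	0.2
M5	CACNA1C	c.694G>C	urine	amplicon_ngs	ND
M5	CACNA1C	c.694G>C	urine	ddpcr	0.2
M5	CACNA1C	c.694G>C	hair	amplicon_ngs	0.05
M5	CACNA1C	c.694G>C	nail	amplicon_ngs	ND
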