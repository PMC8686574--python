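parent	gene	variant	mosaic_by_ngs	tissues_received
M1	USP7	c.238A>T	yes	yes
M2	PTPN11	c.923A>G	yes	yes
M3	PTPN11	c.923A>G	yes	yes
M4	COL11A1	c.3816+2dupT	yes	yes
M5	CACNA1C	c.694G>C	yes	yes
M6	SYNGAP1	c.1782dupC	no	yes
M7	SYNGAP1	c.654_655delCT	no	yes
M8	PUF60	c.628C>T	no	yes
F1	STXBP1	c.1099C>T	no	no
F2	NEDD4L	c.814-6T>A	no	yes
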