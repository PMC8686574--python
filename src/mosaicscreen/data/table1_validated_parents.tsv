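gene	variant	acmg_class	phenotype	inheritance_mode	parent_of_origin	es_vaf_pct	ngs_vaf_pct	ngs_method	ddpcr_vaf_pct
CACNA1C	c.694G>C	VUS	Timothy syndrome [MIM:601005]	AD	maternal	1	2		NA
COL6A3	c.218A>G	VUS	Bethlem myopathy [MIM:58810]	AD/AR	maternal	0.4	0.3		NA
COL11A1	c.3816+2dupT	Pathogenic	Stickler syndrome 2 [MIM:604841]	AD/AR	maternal	2.8	0.2	HC	NA
DLL4	c.586G>A	Likely pathogenic	Adams-Oliver syndrome [MIM:616589]	AD	paternal	2	2		0.05
HUWE1	c.12257G>A	Likely pathogenic	Mental retardation, X-linked, Turner type [MIM:30076]	XL	maternal	0.3	0.1		NA
IFT172	c.4161-1G>A	Pathogenic	Retinitis pigmentosa [MIM:616394]	AR	paternal	3	4		3.8
KIF1A	c.1132C>T	VUS	Polyhydramnios	AD/AR	maternal	2	4		3.7
KIF1A	c.757G>A	Pathogenic	Mental retardation, autosomal dominant 9 [MIM:614255]	AD/AR	paternal	1	0.1		NA
NRXN2	c.3382G>A	VUS	Autism spectrum disorder	AD	maternal	5	6		4.5
PDCD10	c.474+5G>A	Pathogenic	Cerebral cavernous malformations 3 [MIM:603285]	AD	paternal	1	5		NA
PIGA	c.986T>C	Likely pathogenic	Multiple congenital anomalies-hypotonia-seizures syndrome 2 [MIM:300868]	XLR	maternal	2	2		1.83
PTEN	c.542T>C	Pathogenic	Cowden syndrome 1 [MIM:158350]	AD	maternal	2	0.3		NA
PTPN11	c.923A>G	Pathogenic	Noonan syndrome 1 [MIM:163950]	AD	maternal	1	0.3		NA
PTPN11	c.923A>G	Pathogenic	Noonan syndrome 1 [MIM:163950]	AD	maternal	1	0.3		NA
PTPN11	c.922A>G	Pathogenic	Noonan syndrome 1 [MIM:163950]	AD	maternal	1	0.3		NA
RBFOX1	c.474+6T>C	VUS	Autism spectrum disorder	AD	paternal	1	0.2		NA
SMARCA2	c.2254G>A	Likely pathogenic	Nicolaides-Baraitser syndrome [MIM:601358]	AD	paternal	1	0.08		NA
SMARCA4	c.2936G>A	Pathogenic	Coffin-Siris syndrome 4 [MIM:614609]	AD	paternal	4	5		4.76
TPM1	c.475G>A	Likely pathogenic	Cardiomyopathy [MIM:115196]	AD	paternal	2	0.1		NA
USP7	c.238A>T	Likely pathogenic	Intellectual disability and autism spectrum disorder [PMID:26365382]	AD	maternal	3	9		4.13
ZBTB20	c.1916G>A	Likely pathogenic	Primrose syndrome [MIM:259050]	AD	paternal	1	3		NA
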