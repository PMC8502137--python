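# Key-pathway gene map (RTK/RAS/PI3K, p53/cell cycle, cell adhesion, chromatin remodeling); synthetic fixture.
gene	pathway
ERBB2	RTK_RAS_PI3K
HSP90AB1	RTK_RAS_PI3K
MYC	RTK_RAS_PI3K
PIK3CA	RTK_RAS_PI3K
KRAS	RTK_RAS_PI3K
EGFR	RTK_RAS_PI3K
VEGFA	RTK_RAS_PI3K
PTEN	RTK_RAS_PI3K
PREX2	RTK_RAS_PI3K
TP53	p53_cell_cycle
CCNE1	p53_cell_cycle
CCND1	p53_cell_cycle
CCND3	p53_cell_cycle
CDK4	p53_cell_cycle
CDKN2A	p53_cell_cycle
MDM2	p53_cell_cycle
CDH1	cell_adhesion
RHOA	cell_adhesion
ITGAV	cell_adhesion
CTNNB1	cell_adhesion
FAT4	cell_adhesion
APC	cell_adhesion
ARID1A	chromatin_remodeling
SMARCA4	chromatin_remodeling
KMT2C	chromatin_remodeling
KMT2D	chromatin_remodeling
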