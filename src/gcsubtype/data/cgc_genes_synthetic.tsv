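# Curated cancer-gene-census-style subset (synthetic fixture, frozen so results do not drift with database versions).
gene
APC
ARID1A
BRCA1
CCND1
CCND3
CCNE1
CDH1
CDK4
CDKN2A
CTNNB1
EGFR
ERBB2
FAT3
FAT4
HSP90AB1
ITGAV
KMT2C
KMT2D
KRAS
LRP1B
MDM2
MLH1
MYC
NOTCH1
PIK3CA
PREX2
PTEN
RHOA
SMAD4
SMARCA4
SPTA1
SYNE1
TP53
VEGFA
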