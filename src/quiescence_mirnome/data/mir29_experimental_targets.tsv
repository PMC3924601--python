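gene_id	log2_fold_change	function
ARRDC4	-1.19	N/A
BLMH	-1.05	N/A
CDK6	-1.27	Cell cycle
COL1A1	-1.44	ECM
COL3A1	-1.85	ECM
COL5A2	-1.87	ECM
FBN1	-1.27	ECM
FSTL1	-1.51	BMP antag.
LAMC1	-1.06	ECM
MFAP2	-1.11	ECM
PPIC	-1.28	ECM?
RCC2	-1.21	Cell cycle
SERPINH1	-1.09	ECM
SPARC	-1.34	ECM
TBC1D7	-1.12	N/A
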