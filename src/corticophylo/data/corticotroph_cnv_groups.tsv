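sample_id	cytoband	direction	genes
ACTH_CA	10q11.22	gain	SYT15
ACTH_CA	15q11.2	gain	POTEB
ACTH_CA	16p12.3	gain	ARL6IP1
ACTH_CA	1p13.2	gain	HIPK1
ACTH_CA	20p	gain	CJD6
ACTH_CA	8p21.2	loss
CCA	17q12	gain	CCL3L1
CCA	10q11.22	gain	NPY4R
CCA	18q21.1	loss	KATNAL2
CCA	15q12	loss	TUBGCP5
CCA	2q11.2	loss	ANKRD36
SCA	17q22	gain	CCL3L1
SCA	17q12	gain	CCL3L1
SCA	10q11.22	gain	NPY4R
SCA	18q21.1	loss	KATNAL2
SCA	15q12	loss	TUBGCP5
SCA	2q11.2	loss	ANKRD36
CD	17q12	gain	CCL3L1
CD	2p12	gain	CTNNA2
CD	9p24	gain	FOXD4
CD	10q11.22	gain	NPY4R
CD	20p13	gain
CD	21p12	loss	USP16
CD	15q11.2	loss	KLF13
CD	8p23	loss	DEF130A
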