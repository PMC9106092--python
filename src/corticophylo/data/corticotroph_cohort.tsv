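tumor_id	age	sex	clinical_dx	path_dx	max_diameter_mm	cav_sinus_invasion	vision_abnormal	surgeries	snv_genes
1	28	F	cushing_disease	acth_carcinoma	28	Yes	Yes	4 TSS, 1 TCS	USP8, TP53, AURKA, EGFR, HSD3B1, CDKN1A
2	52	M	non_functioning	crooke_cell_adenoma	44	Yes	Yes	1 TSS	TP53, EGFR, HSD3B1, CDKN1A
3	61	F	non_functioning	silent_acth_adenoma	51	Yes	Yes	2 TSS	CDKN1A, HSD3B1, AURKA, TP53
4	45	F	non_functioning	silent_acth_adenoma	45	Yes	Yes	2 TSS, 1 TCS	CDKN1A, EGFR, HSD3B1
5	52	F	non_functioning	silent_acth_adenoma	31	Yes	Yes	1 TSS	CDKN1A, AURKA, TP53, EGFR, HSD3B1
6	54	F	cushing_disease	acth_adenoma	44	Yes	Yes	1 TCS	HSD3B1, TP53,
7	40	F	cushing_disease	acth_adenoma	18	Yes	No	1 TSS	EGFR, TP53, HSDB3B1
8	18	F	cushing_disease	acth_adenoma	18	No	No	2 TSS	HSD3B1, TP53, AURKA,
9	17	F	cushing_disease	acth_adenoma	23	Yes	Yes	1 TCS	HSD3B1, TP53, EGFR
10	21	F	nelson	acth_adenoma	17	Yes	Yes	2 TSS	USP8, TP53, HSD3B1, CDKN1A
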