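# Measured mPSF binding affinities and annotation frequencies of human PAS hexamers.
# label: FAM = 5'-fluorescein-labeled probe oligo; "-" = unlabeled competitor oligo.
# kd_nM / ratio_printed: "nd" = not determined.
sequence	hexamer	label	frequency_percent	kd_nM	ratio_printed
UGCAAUAAACAA	AAUAAA	FAM	60.76	19	0.5
UGCAAUAAACAA	AAUAAA	-	60.76	40	1
UGCAUUAAACAA	AUUAAA	-	16.76	79	2
UGCAGUAAACAA	AGUAAA	-	3.29	194	5
UGCUAUAAACAA	UAUAAA	-	2.92	520	13
UGCAAUAUACAA	AAUAUA	-	2.85	2500	62
UGCAAUACACAA	AAUACA	-	2.18	2200	55
UGCAAGAAACAA	AAGAAA	-	1.58	1870	47
UGCAAUGAACAA	AAUGAA	-	1.57	1180	30
UGCCAUAAACAA	CAUAAA	-	1.49	780	20
UGCGAUAAACAA	GAUAAA	-	1.23	580	14
UGCAACAAACAA	AACAAA	-	1.13	13000	325
UGCAAUAAUCAA	AAUAAU	-	1.12	1170	29
UGCAAUAGACAA	AAUAGA	-	0.71	2000	50
UGCAUUAUACAA	AUUAUA	-	0.58	2140	54
UGCACUAAACAA	ACUAAA	-	0.56	2700	68
UGCAAUAAGCAA	AAUAAG	-	0.53	11500	288
UGCAUUACACAA	AUUACA	-	0.40	nd	nd
UGCAACAAGCAA	AACAAG	-	0.34	nd	nd
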