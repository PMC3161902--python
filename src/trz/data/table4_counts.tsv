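species	n_cca	n_ccn	n_cnn	n_total	printed_percent
Arabidopsis thaliana	0	1	11	37	32
Brachypodium distachyon	1	1	8	38	26
Carica papaya	0	1	8	37	24
Citrus sinensis	2	1	7	37	27
Cucumis sativus	0	1	7	37	22
Eucalyptus grandis	0	1	8	36	25
Glycine max	0	1	9	37	27
Manihot esculenta	0	1	7	37	22
Medicago truncatula	0	0	5	29	17
Oryza sativa japonica	1	2	7	38	26
Populus trichocarpa	0	0	10	37	27
Prunus persica	0	1	8	37	24
Sorghum bicolor	0	2	7	38	24
Vitis vinifera	0	1	8	37	24
Zea mays	1	2	7	37	27
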