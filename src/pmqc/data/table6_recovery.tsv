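analyte	level	spiked_ug_ml	found_ug_ml	found_sd	recovery_printed_pct	rsd_pct
GA	low	0.26	0.26	0.00	98.39	1.19
GA	mid	0.33	0.32	0.01	98.87	1.81
GA	high	0.39	0.39	0.00	98.54	0.04
EM	low	0.90	0.91	0.00	100.75	0.06
EM	mid	1.12	1.13	0.02	100.53	1.43
EM	high	1.35	1.33	0.01	98.73	1.41
THSG	low	23.46	22.83	0.14	97.34	0.63
THSG	mid	29.32	29.43	0.37	100.37	1.26
THSG	high	35.19	34.54	0.40	98.17	1.18
EMG	low	7.35	7.17	0.06	97.56	0.77
EMG	mid	9.19	9.16	0.13	99.75	1.46
EMG	high	11.03	11.07	0.05	100.40	0.43
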