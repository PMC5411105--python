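name	mu_N	sd_N	mu_C	sd_C	conc_N	sd_conc_N	conc_C	sd_conc_C	frac_N	sd_frac_N	frac_C	sd_frac_C
Breast Milk	7.39	1.19	-19.55	1.87	1.61	0.27	49.13	3.63	4.42	0.11	5.46	0.67
Root Cultigens	3.84	1.56	-22.45	1.21	1.09	0.09	41.36	1.34	2.00	0.20	4.40	0.90
Legumes	2.23	1.23	-22.86	0.83	3.82	0.33	41.78	0.41	2.00	0.20	4.40	0.90
Tropical Fruits	3.54	2.14	-23.06	1.92	1.37	0.61	43.46	4.50	2.00	0.20	4.40	0.90
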