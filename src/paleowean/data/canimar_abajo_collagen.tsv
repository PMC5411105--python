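sample_id	cemetery	cohort	age_estimate	age_low_years	age_high_years	d13C	d15N	pctC	pctN	cn_ratio	collagen_yield
E-29	YC	juvenile	Birth-1.5 months			-18.12	9.45	29.60	10.60	2.80	5.60
E-30	YC	juvenile	1.5–3 months			-15.03	12.07	38.20	10.90	3.50	11.20
E-32	YC	juvenile	1.5–3 months			-16.96	9.13	30.70	9.60	3.20	7.30
E-47	YC	juvenile	Perinatal			-19.89	11.81	34.20	10.10	3.40	10.70
E-48	YC	juvenile	Birth-1.5 months			-16.70	13.70	36.30	10.70	3.40	10.50
E-49	YC	juvenile	1.5–3 months			-19.76	6.98	36.10	10.60	3.40	10.30
E-50	YC	juvenile	1.5–3 months			-21.23	9.18	36.10	10.60	3.40	11.30
E-55	OC	juvenile	1.5–3months			-20.40	11.30	36.50	10.70	3.40	6.50
CCC (5)	YC	juvenile	Birth-1.5 months			-19.01	12.53	35.90	10.90	3.30	10.20
CCC (10)	YC	juvenile	1.5–3 months			-21.60	8.29	36.20	10.60	3.40	9.30
C (291)	YC	juvenile	1.5–3 months			-17.57	14.48	36.00	11.30	3.20	2.70
E-26	YC	juvenile	10 months–1 year			-16.83	11.53	35.90	10.60	3.40	10.20
E-34	YC	juvenile	6 months–1 year			-22.80	11.00	37.20	12.00	3.10	8.30
E-46	YC	juvenile	6 months–1 year			-18.33	14.88	36.10	10.60	3.40	10.30
CCC (3)	YC	juvenile	1 year			-22.51	10.92	31.40	9.50	3.30	6.70
C (293)	YC	juvenile	6 months–1 year			-19.68	11.35	36.00	10.60	3.40	10.30
C (295)	YC	juvenile	6 months–1 year			-18.96	11.03	35.80	10.80	3.30	9.20
E-27	YC	juvenile	1.5–2 years			-16.48	10.90	35.90	10.60	3.40	10.50
E-35	YC	juvenile	1.5 years			-17.20	12.05	39.50	11.00	3.60	13.70
E-42	YC	juvenile	1–1.5 years			-18.77	14.17	38.50	11.70	3.30	11.90
E-44	YC	juvenile	1–1.5 years			-22.28	9.18	35.90	10.90	3.30	10.20
E-45	YC	juvenile	1.5–2 years			-18.29	12.99	36.30	10.10	3.60	11.10
E-53	YC	juvenile	1–1.5 years			-17.40	11.31	39.20	11.90	3.30	12.80
E-54	OC	juvenile	1.5–2 years			-15.80	12.00	35.80	11.50	3.10	10.00
CCC (2)	YC	juvenile	1.5–2 years			-20.80	13.36	34.90	11.60	3.00	9.10
E-1	YC	juvenile	3.5 years			-21.50	4.07	32.40	10.80	3.00	5.30
E-28	YC	juvenile	3–3.5 years			-16.47	12.72	37.80	11.10	3.40	13.80
E-58	YC	juvenile	3.5–4 years			-23.28	7.02	35.90	10.30	3.50	10.20
E-64	YC	juvenile	3–3.5 years			-25.61	7.02	36.20	10.60	3.40	7.30
E-65	YC	juvenile	2.5–3 years			-19.28	12.99	35.20	10.40	3.40	9.30
C (4)	YC	juvenile	5–5.5 years			-19.61	9.65	36.30	11.00	3.30	11.50
E-19b	OC	adult_female	Young Adult			-13.03	8.72	31.90	10.60	3.00	6.10
E-21	OC	adult_female	Young Adult			-13.10	12.10	32.70	10.50	3.10	7.30
E-23	OC	adult_female	Young Adult			-13.88	8.99	35.60	12.30	2.90	5.20
E-87	OC	adult_female	Full Adult			-14.30	10.90	34.10	10.70	3.20	9.00
E-88	OC	adult_female	Young Adult			-15.70	10.10	31.90	10.60	3.00	7.40
E-4	YC	adult_female	Young Adult			-13.00	11.40	34.10	10.70	3.20	11.00
E-5	YC	adult_female	Full Adult			-14.80	11.40	37.50	10.40	3.60	12.20
E-10	YC	adult_female	Full Adult			-14.10	9.20	33.10	10.70	3.10	7.10
E-24	YC	adult_female	Full Adult			-10.50	11.50	32.60	10.50	3.10	10.90
E-69	YC	adult_female	Young Adult			-14.30	11.30	38.60	10.70	3.60	13.00
E-70	YC	adult_female	Young Adult			-16.30	11.40	37.20	10.60	3.50	12.20
E-74	YC	adult_female	Mature Adult			-12.60	10.90	30.80	10.60	2.90	6.30
E-75	YC	adult_female	Young Adult			-14.29	9.37	32.90	9.70	3.40	10.30
E-81	YC	adult_female	Full Adult			-14.00	11.20	34.10	10.70	3.20	8.20
E-82	YC	adult_female	Mature Adult			-17.27	12.83	38.70	12.10	3.20	11.40
E-84	YC	adult_female	Young Adult			-18.80	10.80	35.20	10.70	3.30	9.20
E-94	YC	adult_female	Mature Adult			-15.37	11.84	34.20	11.00	3.10	10.90
E-95	YC	adult_female	Mature Adult			-15.33	12.45	33.30	11.10	3.00	9.90
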