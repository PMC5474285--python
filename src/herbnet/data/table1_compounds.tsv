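compound_id	name	ob_percent	caco2	dl
C1	3-Methylcoumarin	19.66	1.27	0.05
C2	5,6,7-Trimethoxycoumarin	32.54	0.94	0.12
C3	AIDS045703	21.37	0.55	0.87
C4	Androstane-3,11,17-triol	13.19	-0.04	0.38
C5	Anemosapogenin	17.87	0.07	0.77
C6	Anemoside A3	15.46	-1.6	0.15
C7	Aureusidin	53.42	0.07	0.24
C8	Beta-sitosterol	36.91	1.32	0.75
C9	Betulonic acid	16.83	0.65	0.78
C10	Campesterol	5.57	1.6	0.72
C11	Cauloside A	6.84	-0.82	0.4
C12	Cernuoside	2.69	-1.51	-2.18
C13	Dauricine (8CI)	23.65	0.9	0.37
C14	Ergosterol	14.29	1.47	0.72
C15	Fraxinol	24.19	0.7	0.1
C16	Hederagenol	22.42	0.1	0.74
C17	Isorhamnetin	49.6	0.31	0.31
C18	LAN	42.12	1.52	0.75
C19	Lignoceric acid	14.9	1.24	0.33
C20	Mairin	55.38	0.73	0.78
C21	Oleanolic acid	29.02	0.59	0.76
C22	Oleanolic acid deriv.	14.24	0.65	0.7
C23	Pinoresinol	4.25	0.52	0.52
C24	Pulchinenoside A_qt	16.91	0.12	0.77
C25	Scoparone	74.75	0.85	0.09
C26	Sitogluside	20.63	-0.14	0.62
C27	Sitosteryl acetate	40.39	1.39	0.85
C28	Stigmasterol	43.83	1.44	0.76
C29	Tricosanoic acid	15.29	1.18	0.3
C30	Ursolic acid	16.77	0.67	0.75
C31	ZINC01615307	56.38	0.53	0.87
C32	beta-Sitosterol	5.84	1.42	0.71
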