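locus	group	forward	reverse	n_alleles	size_min_bp	size_max_bp	he	ho	fis	pid	pid_sib	amplifies_tapir	may_amplify_human	note
Disu033	highly_recommended	TCTGGATACCTGAGGCTTGAC	ACTGGCATCACTTCTTTCCC	2	152	164	0.53	0.00	1.00	0.41	0.63	0	0	.
Disu098	highly_recommended	GCTAGGAGAGGGTGTTGGAC	TGGTAGCCTTGCCTCTTTCC	4	98	126	0.78	0.20	0.76	0.14	0.44	0	0	.
Disu100	highly_recommended	TGTGGACTTGTCATATATGGGC	TTCATCCATGCTGTCACAAATG	2	120	122	0.36	0.40	-0.14	0.51	0.72	0	0	exceptional
Disu201	highly_recommended	TGGAGAGAATTTCAGACATGGG	CTAGCCCAAGATCCATTGGC	2	156	158	0.53	0.00	1.00	0.39	0.61	1	0	.
Disu261	highly_recommended	AAACCATACGCGGGAGAAGG	GAAGGGAAGATCATGCAGGAG	2	150	166	0.60	0.33	0.50	0.38	0.59	0	0	.
Disu393	highly_recommended	AGTGAGCAAGGGAATGTGTG	GGGTGCTGTCTCTTGATTGG	2	155	157	0.36	0.40	-0.14	0.51	0.72	0	0	.
Disu448	highly_recommended	CAGGTTTCGTTACTGCAGGAC	TCTGGTGACCTGAGATGCAC	2	154	156	0.20	0.20	NA	0.69	0.83	0	0	exceptional
Disu476	highly_recommended	AAACAGGGAAACAAGGTGCG	GACTGCGCCCTTTCTGTTAG	3	162	174	0.60	0.80	-0.39	0.29	0.55	0	0	exceptional
Disu487	highly_recommended	TATCATGTCACAAGCACGCG	GTCTTCTTCACGACAGCACC	2	148	160	0.20	0.20	NA	0.69	0.83	1	0	exceptional
Disu783	highly_recommended	CCTTGCCTTGCCTTCAATCC	CCATCCTTTCTCCTACACAGAC	3	126	134	0.51	0.60	-0.20	0.34	0.61	0	0	exceptional
Disu847	highly_recommended	AAAGTCGCCTCTCACACACC	TCAGAGCCTCCTTGTAAGCG	2	138	140	0.20	0.20	NA	0.69	0.83	0	0	.
Disu050	recommended	CTCCCACATTCAGCAAACTTTC	CCAGGCAGTGATGACTCTAC	3	160	166	0.51	0.20	0.64	0.34	0.61	0	0	.
Disu071	recommended	TTGAGATGCATTGCCGTGG	CCATGGTTTCTGCATCGTGG	3	168	172	0.73	0.33	0.60	0.23	0.50	1	1	.
Disu076	recommended	TTCCAGCCGCTCTTATGACC	TCATGTGCTTATTGGCCATCTG	2	125	129	0.53	0.00	1.00	0.41	0.63	0	1	.
Disu127	recommended	CCACCACCACCATGCATAG	CATTTGCTCCCATGCTGAAG	2	162	164	0.36	0.00	1.00	0.51	0.72	0	0	.
Disu138	recommended	GGGACACATGACTCCTCTTATC	CCACTCCACCTTATACTACCAC	2	167	169	0.53	0.00	1.00	0.41	0.63	0	0	.
Disu149	recommended	GAGCGTGCATGGTAGTTTCC	GGTTCTCATAGCAGACGGAG	4	160	168	0.73	1.00	-0.43	0.18	0.47	0	0	.
Disu151	recommended	CATTGTGCTCGCTACGCAG	CTAGGTGTCAAGAGCCAGGG	2	135	137	0.36	0.00	1.00	0.51	0.72	1	1	.
Disu480	recommended	CCTGCCTTCTAGTCCTGTGG	AGCAAGCAGGATCAGGAAGG	2	112	116	0.47	0.20	0.60	0.42	0.65	0	0	.
Disu501	recommended	TGGCCACATCTTCAGCATTAAG	GCACCTAACACAGTTACAGGC	2	155	157	0.47	0.60	-0.33	0.42	0.65	0	0	.
Disu542	recommended	AAACTACAGGCACGTACAGC	TTGAGAGATGAGGTGCGGTC	2	128	130	0.20	0.20	NA	0.69	0.83	1	1	.
Disu545	recommended	TGTTGTCCAAGCTGTGTCTG	TGGCAGCTGGTACCTAACAG	2	148	150	0.20	0.20	NA	0.69	0.83	0	0	.
Disu556	recommended	GCCAATTAAATCTACCTGCCAC	GCCAAGACTCAAACCCAGG	2	168	174	0.25	0.25	NA	0.63	0.80	0	1	.
Disu582	recommended	TCTGTGGTGGTAGCTGTGAC	TGGCACAGAGACACCCATG	2	144	152	0.36	0.00	1.00	0.51	0.72	0	0	.
Disu593	recommended	CCACGTCCCAGGTCAAGAG	AGCTGTTCCTGGTGGCTC	3	164	166	0.56	0.20	0.67	0.38	0.59	1	1	.
Disu733	recommended	TGGCACAGAGACACCCATG	TCTGTGGTGGTAGCTGTGAC	2	151	159	0.36	0.00	1.00	0.51	0.72	0	0	.
Disu748	recommended	CCTTGATTGGTGGGTTCCC	AGAGAGAGCGCACGTGTG	3	106	116	0.64	0.80	-0.28	0.26	0.53	1	0	.
Disu269	not_recommended	CAAGACCACACCTGCTTGTC	ACTCACTCATCACCCAGCC	3	115	152	0.60	0.33	0.50	0.30	0.58	1	1	failed_to_amplify
Disu863	not_recommended	GAAGCTGTATGTCCGGATGC	GCTAAACAGACCTTCCTCAGAG	2	162	166	0.36	0.40	-0.14	0.51	0.72	1	1	monomorphic_in_field_samples
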