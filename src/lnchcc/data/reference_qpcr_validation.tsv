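transcript_id	chromosome	ncrna_type	micro_h1	micro_h2	micro_h3	qpcr_h1	qpcr_h2	qpcr_h3
AK056250	chr1	intergenic	2.86	2.39	1.85	1.16	0.96	1.03
BC013423	chr5	intergenic	2.62	2.62	4.93	1.49	1.50	2.90
BC017743	chr3	intron sense-overlapping	5.41	1.31	3.54	3.81	0.20	0.04
ENST00000394293	chr7	intergenic	1.20	2.07	1.34	0.19	0.99	0.61
ENST00000417262	chr1	intergenic	2.74	1.60	3.01	2.29	0.87	0.75
NR_002734	chr8	intronic antisense	3.64	2.13	3.19	3.18	1.71	3.23
NR_003573	chr9	intergenic	2.50	1.21	2.96	2.16	1.26	1.49
uc001vvq.1	chr14	intergenic	1.75	3.70	5.79	0.16	0.86	1.04
uc003gzp.2	chr4	intergenic	3.23	1.03	2.56	2.59	0.90	0.86
ENST00000447956	chr20	intergenic	3.73	4.03	2.91	2.83	3.26	1.17
NR_027355	chr1	intergenic	1.95	1.15	3.59	1.00	0.86	3.24
uc001tvk.1	chr12	intergenic	4.92	4.03	4.30	2.87	0.78	3.69
uc002odt.1	chr19	intergenic	4.84	2.22	5.36	4.64	0.97	0.93
uc001sqo.2	chr12	intergenic	1.50	3.21	4.68	2.06	1.58	1.54
ENST00000421424	chr20	intergenic	-6.38	-2.73	-1.96	-5.50	-2.14	-2.32
ENST00000423174	chr3	intergenic	-2.84	-1.84	-5.87	-1.79	-2.16	-1.94
ENST00000502804	chr4	intergenic	-4.28	-2.75	-1.95	-3.22	-4.00	-1.67
ENST00000504368	chr4	intergenic	-1.90	-2.77	-7.48	-2.75	-2.16	-9.42
X91348	chr22	intergenic	-3.68	-2.92	-4.39	-2.83	-2.37	-0.33
ENST00000449772	chr2	intergenic	-2.59	-1.99	-2.59	-3.54	-4.10	-5.74
ENST00000437516	chr6	intergenic	-9.53	-1.02	-1.42	-0.51	-0.23	-2.84
ENST00000418694	chr9	intergenic	-2.87	-1.43	-3.22	-1.24	-0.79	-2.20
ENST00000451163	chr2	intergenic	-3.26	-7.76	-5.81	-1.45	-2.12	-2.40
ENST00000489312	chr4	natural antisense	-6.79	-1.18	-1.87	0.07	0.30	-2.66
NR_033646	chr16	exon sense-overlapping	-3.66	-1.15	-6.74	-1.26	-1.38	-2.51
uc010ytt.1	chr2	intergenic	-2.96	-7.66	-7.14	-3.75	-8.17	-6.38
AK124428	chr5	intergenic	-2.01	-1.48	-1.44	-2.45	-1.54	-1.24
AK129699	chr7	intergenic	-1.81	-2.35	-2.84	-2.14	-2.57	-3.52
ENST00000377415	chr9	intergenic	-1.68	-4.91	-4.89	-1.61	-5.20	-5.37
ENST00000398087	chr7	intergenic	-2.92	-2.12	-6.30	-3.68	-1.09	-7.82
NR_002712	chr2	intergenic	-4.32	-3.74	-1.91	-2.90	-3.49	-4.97
NR_026643	chr11	intronic antisense	-2.99	-1.04	-5.62	-4.08	-1.06	-7.73
NR_026743	chr10	intergenic	-3.29	-2.07	-4.09	-5.13	-1.22	-9.23
NR_027151	chr10	intronic antisense	-3.69	-5.79	-5.69	-2.83	-3.11	-5.63
NR_033661	chr22	exon sense-overlapping	-2.18	-4.55	-4.42	3.05	-5.67	-3.63
ENST00000416474	chr2	intergenic	-3.61	-7.65	-4.93	-2.17	-0.74	-0.61
ENST00000417888	chr10	intergenic	-2.56	-3.43	-1.97	1.88	-1.31	-3.18
AK056988	chr11	intronic antisense	-4.15	-1.32	-2.99	-5.39	-2.34	-3.82
U70031	chr2	intergenic	-3.40	-8.10	-3.68	-2.47	-5.72	-5.39
uc003yqb.1	chr8	intronic antisense	-3.92	-1.09	-5.34	-6.66	-2.80	-6.97
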