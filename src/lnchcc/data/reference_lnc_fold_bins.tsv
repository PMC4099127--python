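patient_id	direction	fold_2_4	fold_4_6	fold_gt6
H1	up	1917	461	335
H1	down	1120	235	301
H2	up	1393	301	240
H2	down	1033	177	168
H3	up	1314	665	1901
H3	down	1898	628	687
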