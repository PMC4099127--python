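patient_id	direction	fold_2_4	fold_4_6	fold_gt6
H1	up	2295	487	428
H1	down	1852	419	596
H2	up	2001	380	326
H2	down	1595	381	449
H3	up	1831	918	2402
H3	down	2709	885	1365
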