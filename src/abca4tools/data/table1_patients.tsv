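patient_id	sex	onset_age	exam_age	acuity_od	acuity_os	fundus_type	af_type	erg_type	severity_label	group_label	evaluable
1	F	7	8	1.40	1.30		1		3	C	1
2	F	12	16	1.30	1.30		2		2	C	1
3	F	7	8	1.12	1.12		1		3	C	1
4	M	55	57	0.40	0.15		3		1	B	1
5	F	7	13	1	1				3	C	1
6	M	52	52	FC/40cm	FC/30cm		3		3	A	1
7	F	8	9	0.92	1		2		2	B	1
8	M	11	13	0.70	0.82		1		1	A	1
9	M	11	31	1	1		2		2	B	1
10	M	6	6	1.15	1		1		3	B	1
11	M	25	25	1.10	1					C	0
12	M	17	17	1	0.92		2		2	B	1
13	F	14	19	1	1					B	0
14	F	41	41	0	0.10				1	A	0
15	M	7	13	0.49	0.60		2		2	C	1
16	F	46	47	0.40	0.60		2		1	A	1
17	F	47	50	0.60	0.49		3		1	A	1
18	M	8	15	1.70	1.15		3		3	C	1
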