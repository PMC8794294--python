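patient_id	age	sex	laterality	pain_procedures	nerve_block	vrs_pre	vrs_post	vrs_discharge
1	17	F	R	3	Y	NA	NA	NA
2	19	F	L	3	N	NA	NA	NA
3	17	F	R	5	N	NA	NA	NA
4	13	F	R	4	Y	NA	NA	NA
5	14	M	R	8	Y	NA	NA	NA
6	16	F	R	2	N	NA	NA	NA
7	18	M	R	5	Y	NA	NA	NA
8	19	M	L	5	Y	NA	NA	NA
9	22	F	R	6	Y	NA	NA	NA
10	14	F	R	5	Y	NA	NA	NA
11	23	M	L	6	N	NA	NA	NA
12	16	M	L	6	Y	NA	NA	NA
13	25	F	L	6	Y	NA	NA	NA
14	17	F	R	2	N	NA	NA	NA
15	22	M	R	2	N	NA	NA	NA
16	17	M	L	11	Y	NA	NA	NA
17	19	F	L	9	Y	NA	NA	NA
18	21	F	R	12	N	NA	NA	NA
19	16	M	R	10	N	NA	NA	NA
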