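feature	label	lower	upper	kind
BP10MB	BP10MB[0]	0	0	discrete
BP10MB	BP10MB[1]	1	1	discrete
BP10MB	BP10MB[2]	2	2	discrete
BP10MB	BP10MB[3]	3	3	discrete
BP10MB	BP10MB[4]	4	4	discrete
BP10MB	BP10MB[5]	5	5	discrete
BP10MB	BP10MB[>5]	5	inf	range
BPArm	BPArm[0]	0	0	discrete
BPArm	BPArm[1]	1	1	discrete
BPArm	BPArm[2]	2	2	discrete
BPArm	BPArm[3]	3	3	discrete
BPArm	BPArm[4]	4	4	discrete
BPArm	BPArm[5]	5	5	discrete
BPArm	BPArm[6]	6	6	discrete
BPArm	BPArm[7]	7	7	discrete
BPArm	BPArm[8]	8	8	discrete
BPArm	BPArm[9]	9	9	discrete
BPArm	BPArm[>9]	9	inf	range
CN	CN[0]	0	0	discrete
CN	CN[1]	1	1	discrete
CN	CN[2]	2	2	discrete
CN	CN[3]	3	3	discrete
CN	CN[4]	4	4	discrete
CN	CN[5]	5	5	discrete
CN	CN[6]	6	6	discrete
CN	CN[7]	7	7	discrete
CN	CN[8]	8	8	discrete
CN	CN[>8]	8	inf	range
CNCP	CNCP[0]	0	0	discrete
CNCP	CNCP[1]	1	1	discrete
CNCP	CNCP[2]	2	2	discrete
CNCP	CNCP[3]	3	3	discrete
CNCP	CNCP[4]	4	4	discrete
CNCP	CNCP[5]	5	5	discrete
CNCP	CNCP[>5]	5	inf	range
OsCN	OsCN[0]	0	0	discrete
OsCN	OsCN[1]	1	1	discrete
OsCN	OsCN[2]	2	2	discrete
OsCN	OsCN[3]	3	3	discrete
OsCN	OsCN[>3]	3	inf	range
SS	SS[<=2]	-inf	2	range
SS	SS[2-3]	2	3	range
SS	SS[3-4]	3	4	range
SS	SS[4-5]	4	5	range
SS	SS[5-5.5]	5	5.5	range
SS	SS[5.5-6]	5.5	6	range
SS	SS[6-6.5]	6	6.5	range
SS	SS[6.5-7]	6.5	7	range
SS	SS[7-7.5]	7	7.5	range
SS	SS[7.5-8]	7.5	8	range
SS	SS[8-8.5]	8	8.5	range
SS	SS[8.5-9]	8.5	9	range
SS	SS[>9]	9	inf	range
NC50	NC50[<=1]	-inf	1	range
NC50	NC50[2]	2	2	discrete
NC50	NC50[3]	3	3	discrete
NC50	NC50[>3]	3	inf	range
BoChr	BoChr[1]	1	1	discrete
BoChr	BoChr[2]	2	2	discrete
BoChr	BoChr[3]	3	3	discrete
BoChr	BoChr[4]	4	4	discrete
BoChr	BoChr[5]	5	5	discrete
BoChr	BoChr[6]	6	6	discrete
BoChr	BoChr[7]	7	7	discrete
BoChr	BoChr[8]	8	8	discrete
BoChr	BoChr[9]	9	9	discrete
BoChr	BoChr[10]	10	10	discrete
BoChr	BoChr[11]	11	11	discrete
BoChr	BoChr[12]	12	12	discrete
BoChr	BoChr[13]	13	13	discrete
BoChr	BoChr[14]	14	14	discrete
BoChr	BoChr[15]	15	15	discrete
BoChr	BoChr[16]	16	16	discrete
BoChr	BoChr[17]	17	17	discrete
BoChr	BoChr[18]	18	18	discrete
BoChr	BoChr[19]	19	19	discrete
BoChr	BoChr[20]	20	20	discrete
BoChr	BoChr[21]	21	21	discrete
BoChr	BoChr[22]	22	22	discrete
BoChr	BoChr[23]	23	23	discrete
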