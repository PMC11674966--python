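gene_id	chromosome	cytoband
SYN1p_01	1	1p11
SYN1p_02	1	1p12
SYN1p_03	1	1p13
SYN1p_04	1	1p14
SYN1p_05	1	1p15
SYN1q_01	1	1q11
SYN1q_02	1	1q12
SYN1q_03	1	1q13
SYN1q_04	1	1q14
SYN1q_05	1	1q15
SYN2p_01	2	2p11
SYN2p_02	2	2p12
SYN2p_03	2	2p13
SYN2p_04	2	2p14
SYN2p_05	2	2p15
SYN2q_01	2	2q11
SYN2q_02	2	2q12
SYN2q_03	2	2q13
SYN2q_04	2	2q14
SYN2q_05	2	2q15
SYN3p_01	3	3p11
SYN3p_02	3	3p12
SYN3p_03	3	3p13
SYN3p_04	3	3p14
SYN3p_05	3	3p15
SYN3q_01	3	3q11
SYN3q_02	3	3q12
SYN3q_03	3	3q13
SYN3q_04	3	3q14
SYN3q_05	3	3q15
SYN4p_01	4	4p11
SYN4p_02	4	4p12
SYN4p_03	4	4p13
SYN4p_04	4	4p14
SYN4p_05	4	4p15
SYN4q_01	4	4q11
SYN4q_02	4	4q12
SYN4q_03	4	4q13
SYN4q_04	4	4q14
SYN4q_05	4	4q15
SYN5p_01	5	5p11
SYN5p_02	5	5p12
SYN5p_03	5	5p13
SYN5p_04	5	5p14
SYN5p_05	5	5p15
SYN5q_01	5	5q11
SYN5q_02	5	5q12
SYN5q_03	5	5q13
SYN5q_04	5	5q14
SYN5q_05	5	5q15
SYN6p_01	6	6p11
SYN6p_02	6	6p12
SYN6p_03	6	6p13
SYN6p_04	6	6p14
SYN6p_05	6	6p15
SYN6q_01	6	6q11
SYN6q_02	6	6q12
SYN6q_03	6	6q13
SYN6q_04	6	6q14
SYN6q_05	6	6q15
SYN7p_01	7	7p11
SYN7p_02	7	7p12
SYN7p_03	7	7p13
SYN7p_04	7	7p14
SYN7p_05	7	7p15
SYN7q_01	7	7q11
SYN7q_02	7	7q12
SYN7q_03	7	7q13
SYN7q_04	7	7q14
SYN7q_05	7	7q15
SYN8p_01	8	8p11
SYN8p_02	8	8p12
SYN8p_03	8	8p13
SYN8p_04	8	8p14
SYN8p_05	8	8p15
SYN8q_01	8	8q11
SYN8q_02	8	8q12
SYN8q_03	8	8q13
SYN8q_04	8	8q14
SYN8q_05	8	8q15
SYN9p_01	9	9p11
SYN9p_02	9	9p12
SYN9p_03	9	9p13
SYN9p_04	9	9p14
SYN9p_05	9	9p15
SYN9q_01	9	9q11
SYN9q_02	9	9q12
SYN9q_03	9	9q13
SYN9q_04	9	9q14
SYN9q_05	9	9q15
SYN10p_01	10	10p11
SYN10p_02	10	10p12
SYN10p_03	10	10p13
SYN10p_04	10	10p14
SYN10p_05	10	10p15
SYN10q_01	10	10q11
SYN10q_02	10	10q12
SYN10q_03	10	10q13
SYN10q_04	10	10q14
SYN10q_05	10	10q15
SYN11p_01	11	11p11
SYN11p_02	11	11p12
SYN11p_03	11	11p13
SYN11p_04	11	11p14
SYN11p_05	11	11p15
SYN11q_01	11	11q11
SYN11q_02	11	11q12
SYN11q_03	11	11q13
SYN11q_04	11	11q14
SYN11q_05	11	11q15
SYN12p_01	12	12p11
SYN12p_02	12	12p12
SYN12p_03	12	12p13
SYN12p_04	12	12p14
SYN12p_05	12	12p15
SYN12q_01	12	12q11
SYN12q_02	12	12q12
SYN12q_03	12	12q13
SYN12q_04	12	12q14
SYN12q_05	12	12q15
SYN13q_01	13	13q11
SYN13q_02	13	13q12
SYN13q_03	13	13q13
SYN13q_04	13	13q14
SYN13q_05	13	13q15
SYN14q_01	14	14q11
SYN14q_02	14	14q12
SYN14q_03	14	14q13
SYN14q_04	14	14q14
SYN14q_05	14	14q15
SYN15q_01	15	15q11
SYN15q_02	15	15q12
SYN15q_03	15	15q13
SYN15q_04	15	15q14
SYN15q_05	15	15q15
SYN16p_01	16	16p11
SYN16p_02	16	16p12
SYN16p_03	16	16p13
SYN16p_04	16	16p14
SYN16p_05	16	16p15
SYN16q_01	16	16q11
SYN16q_02	16	16q12
SYN16q_03	16	16q13
SYN16q_04	16	16q14
SYN16q_05	16	16q15
SYN17p_01	17	17p11
SYN17p_02	17	17p12
SYN17p_03	17	17p13
SYN17p_04	17	17p14
SYN17p_05	17	17p15
SYN17q_01	17	17q11
SYN17q_02	17	17q12
SYN17q_03	17	17q13
SYN17q_04	17	17q14
SYN17q_05	17	17q15
SYN18p_01	18	18p11
SYN18p_02	18	18p12
SYN18p_03	18	18p13
SYN18p_04	18	18p14
SYN18p_05	18	18p15
SYN18q_01	18	18q11
SYN18q_02	18	18q12
SYN18q_03	18	18q13
SYN18q_04	18	18q14
SYN18q_05	18	18q15
SYN19p_01	19	19p11
SYN19p_02	19	19p12
SYN19p_03	19	19p13
SYN19p_04	19	19p14
SYN19p_05	19	19p15
SYN19q_01	19	19q11
SYN19q_02	19	19q12
SYN19q_03	19	19q13
SYN19q_04	19	19q14
SYN19q_05	19	19q15
SYN20p_01	20	20p11
SYN20p_02	20	20p12
SYN20p_03	20	20p13
SYN20p_04	20	20p14
SYN20p_05	20	20p15
SYN20q_01	20	20q11
SYN20q_02	20	20q12
SYN20q_03	20	20q13
SYN20q_04	20	20q14
SYN20q_05	20	20q15
SYN21q_01	21	21q11
SYN21q_02	21	21q12
SYN21q_03	21	21q13
SYN21q_04	21	21q14
SYN21q_05	21	21q15
SYN22q_01	22	22q11
SYN22q_02	22	22q12
SYN22q_03	22	22q13
SYN22q_04	22	22q14
SYN22q_05	22	22q15
SYNXp_01	X	Xp11
SYNXp_02	X	Xp12
SYNXp_03	X	Xp13
SYNXp_04	X	Xp14
SYNXp_05	X	Xp15
SYNXq_01	X	Xq11
SYNXq_02	X	Xq12
SYNXq_03	X	Xq13
SYNXq_04	X	Xq14
SYNXq_05	X	Xq15
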