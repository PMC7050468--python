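spring	basin	temp_c_min	temp_c_max	pH	latitude	longitude	S2	CaCO	Ca	Cl	Mg	SiO2	Na	SO4	K	As	B	Fe	Mn	Zn
Mushroom Spring	Lower Geyser Basin	58.9	60.7	8.3	44.54	-110.80	0	250	0.5	270	1	110	270	22	19	1.7	3	0.02	0.01	0.02
Octopus Spring Low	Lower Geyser Basin	51.0	54.0	8.2	44.53	-110.80	0	300	0.5	310	1	120	300	21	15	1.5	3.5	0.02	0.01	0.02
Octopus Spring Med	Lower Geyser Basin	54.0	64.0	8.2	44.53	-110.80	0.1	290	0.5	290	1	110	300	26	15	1.4	3.3	0.02	0.01	0.02
Octopus Spring High	Lower Geyser Basin	64.0	64.0	8.5	44.53	-110.80	0.1	280	0.5	270	1	100	300	23	15	1.4	3.3	0.02	0.01	0.02
Twin Butte Vista	Lower Geyser Basin	59.3	60.7	8.4	44.54	-110.80	0.6	270	0.5	320	1	110	290	21	13	2.1	3.3	0.02	0.01	0.02
Clearwater East	Clearwater Springs	57.3	61.9	5.2	44.79	-110.74	1.3	8	6	130	1	40	74	26	16	0.68	2.7	0.53	0.04	0.02
Clearwater South	Clearwater Springs	56.3	56.5	6.1	44.79	-110.74	0.2	31	7	140	1	45	94	33	20	0.67	2.8	0.14	0.1	0.02
Heart Pool	West Thumb	56.6	58.3	9.2	44.43	-110.58	20	480	0.5	350	1	120	410	44	23	2.1	4.3	0.02	0.01	0.02
Mantrap Spring	West Thumb	58.2	61.8	8.3	44.42	-110.57	0	350	0.5	180	1	94	270	29	12	1	2.5	0.02	0.01	0.02
Bath Lake Vista	Mammoth Hot Springs	57.0	57.3	6.6	44.96	-110.71	39	720	330	170	63	27	120	600	55	0.94	4.7	0.02	0.01	0.02
New Mound	Mammoth Hot Springs	56.4	56.4	6.6	44.96	-110.71	25	720	350	160	65	27	120	600	54	0.82	4.3	0.07	0.01	0.02
White Elephant Back	Mammoth Hot Springs	59.7	60.0	6.9	44.96	-110.71	8.2	610	330	170	67	30	120	670	54	0.75	4.4	0.22	0.01	0.07
LaDuke Spring	LaDuke	59.8	60.2	6.7	45.10	-110.78	0	230	340	49	59	23	220	1300	24	0.2	0.9	0.19	0.01	0.02
Bozeman Spring	Bozeman	57.2	57.5	8.8	45.66	-111.19	7.7	87	1	53	1	34	130	130	2	0.11	0.6	0.02	0.01	0.02
Jack's Spring Low	Oregon Springs	49.7	50.2	8.4	42.22	-120.37	0.7	65	9	130	1	74	200	280	9	0.02	7.5	0.02	0.01	0.02
Jack's Spring High	Oregon Springs	59.8	61.2	8.3	42.22	-120.37	2.5	64	9	130	1	73	190	270	8	0.15	7.4	0.02	0.01	0.02
Levee Spring	Oregon Springs	59.5	61.8	8.1	42.22	-120.37	5.5	72	10	120	1	71	190	260	9	0.13	7.2	0.02	0.01	0.02
Perpetual Spring	Oregon Springs	60.1	60.9	8.2	42.22	-120.37	4.6	64	10	120	1	73	190	260	9	0.15	7.4	0.02	0.01	0.02
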